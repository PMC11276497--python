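# Independence model: binding memory (P_B) can yield the target on its own;
# otherwise item memory (P_I) supports rejecting the new probe with a target/lure
# guess (g_B); with no memory, g_I splits an "old-looking" guess (then g_B) from
# a "new" guess.
const g_B = 0.5
const g_I = 0.5

intrinsic_consistent target P_B_intrinsic_consistent
intrinsic_consistent target (1-P_B_intrinsic_consistent)*P_I_intrinsic_consistent*g_B
intrinsic_consistent lure (1-P_B_intrinsic_consistent)*P_I_intrinsic_consistent*(1-g_B)
intrinsic_consistent target (1-P_B_intrinsic_consistent)*(1-P_I_intrinsic_consistent)*g_I*g_B
intrinsic_consistent lure (1-P_B_intrinsic_consistent)*(1-P_I_intrinsic_consistent)*g_I*(1-g_B)
intrinsic_consistent new (1-P_B_intrinsic_consistent)*(1-P_I_intrinsic_consistent)*(1-g_I)
intrinsic_inconsistent target P_B_intrinsic_inconsistent
intrinsic_inconsistent target (1-P_B_intrinsic_inconsistent)*P_I_intrinsic_inconsistent*g_B
intrinsic_inconsistent lure (1-P_B_intrinsic_inconsistent)*P_I_intrinsic_inconsistent*(1-g_B)
intrinsic_inconsistent target (1-P_B_intrinsic_inconsistent)*(1-P_I_intrinsic_inconsistent)*g_I*g_B
intrinsic_inconsistent lure (1-P_B_intrinsic_inconsistent)*(1-P_I_intrinsic_inconsistent)*g_I*(1-g_B)
intrinsic_inconsistent new (1-P_B_intrinsic_inconsistent)*(1-P_I_intrinsic_inconsistent)*(1-g_I)
extrinsic_consistent target P_B_extrinsic_consistent
extrinsic_consistent target (1-P_B_extrinsic_consistent)*P_I_extrinsic_consistent*g_B
extrinsic_consistent lure (1-P_B_extrinsic_consistent)*P_I_extrinsic_consistent*(1-g_B)
extrinsic_consistent target (1-P_B_extrinsic_consistent)*(1-P_I_extrinsic_consistent)*g_I*g_B
extrinsic_consistent lure (1-P_B_extrinsic_consistent)*(1-P_I_extrinsic_consistent)*g_I*(1-g_B)
extrinsic_consistent new (1-P_B_extrinsic_consistent)*(1-P_I_extrinsic_consistent)*(1-g_I)
extrinsic_inconsistent target P_B_extrinsic_inconsistent
extrinsic_inconsistent target (1-P_B_extrinsic_inconsistent)*P_I_extrinsic_inconsistent*g_B
extrinsic_inconsistent lure (1-P_B_extrinsic_inconsistent)*P_I_extrinsic_inconsistent*(1-g_B)
extrinsic_inconsistent target (1-P_B_extrinsic_inconsistent)*(1-P_I_extrinsic_inconsistent)*g_I*g_B
extrinsic_inconsistent lure (1-P_B_extrinsic_inconsistent)*(1-P_I_extrinsic_inconsistent)*g_I*(1-g_B)
extrinsic_inconsistent new (1-P_B_extrinsic_inconsistent)*(1-P_I_extrinsic_inconsistent)*(1-g_I)
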