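# Independence model: binding memory (P_B) can yield the target on its own;
# otherwise item memory (P_I) supports rejecting the new probe with a target/lure
# guess (g_B); with no memory, g_I splits an "old-looking" guess (then g_B) from
# a "new" guess.
const g_B = 0.5
const g_I = 0.5

intrinsic_shape target P_B_intrinsic_shape
intrinsic_shape target (1-P_B_intrinsic_shape)*P_I_intrinsic_shape*g_B
intrinsic_shape lure (1-P_B_intrinsic_shape)*P_I_intrinsic_shape*(1-g_B)
intrinsic_shape target (1-P_B_intrinsic_shape)*(1-P_I_intrinsic_shape)*g_I*g_B
intrinsic_shape lure (1-P_B_intrinsic_shape)*(1-P_I_intrinsic_shape)*g_I*(1-g_B)
intrinsic_shape new (1-P_B_intrinsic_shape)*(1-P_I_intrinsic_shape)*(1-g_I)
intrinsic_colour target P_B_intrinsic_colour
intrinsic_colour target (1-P_B_intrinsic_colour)*P_I_intrinsic_colour*g_B
intrinsic_colour lure (1-P_B_intrinsic_colour)*P_I_intrinsic_colour*(1-g_B)
intrinsic_colour target (1-P_B_intrinsic_colour)*(1-P_I_intrinsic_colour)*g_I*g_B
intrinsic_colour lure (1-P_B_intrinsic_colour)*(1-P_I_intrinsic_colour)*g_I*(1-g_B)
intrinsic_colour new (1-P_B_intrinsic_colour)*(1-P_I_intrinsic_colour)*(1-g_I)
extrinsic_shape target P_B_extrinsic_shape
extrinsic_shape target (1-P_B_extrinsic_shape)*P_I_extrinsic_shape*g_B
extrinsic_shape lure (1-P_B_extrinsic_shape)*P_I_extrinsic_shape*(1-g_B)
extrinsic_shape target (1-P_B_extrinsic_shape)*(1-P_I_extrinsic_shape)*g_I*g_B
extrinsic_shape lure (1-P_B_extrinsic_shape)*(1-P_I_extrinsic_shape)*g_I*(1-g_B)
extrinsic_shape new (1-P_B_extrinsic_shape)*(1-P_I_extrinsic_shape)*(1-g_I)
extrinsic_colour target P_B_extrinsic_colour
extrinsic_colour target (1-P_B_extrinsic_colour)*P_I_extrinsic_colour*g_B
extrinsic_colour lure (1-P_B_extrinsic_colour)*P_I_extrinsic_colour*(1-g_B)
extrinsic_colour target (1-P_B_extrinsic_colour)*(1-P_I_extrinsic_colour)*g_I*g_B
extrinsic_colour lure (1-P_B_extrinsic_colour)*(1-P_I_extrinsic_colour)*g_I*(1-g_B)
extrinsic_colour new (1-P_B_extrinsic_colour)*(1-P_I_extrinsic_colour)*(1-g_I)
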