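>J_HEAVY_JH3 start=103 synthetic stand-in FR4 segment
WGQGTMVTVSS
>J_HEAVY_JH4 start=103 synthetic stand-in FR4 segment
WGQGTLVTVSS
>J_HEAVY_JH6 start=103 synthetic stand-in FR4 segment
WGQGTTVTVSS
>J_LIGHT_JK1 start=98 synthetic stand-in FR4 segment
FGQGTKVEIK
>J_LIGHT_JK2 start=98 synthetic stand-in FR4 segment
FGQGTKLEIK
>J_LIGHT_JK4 start=98 synthetic stand-in FR4 segment
FGGGTKVEIK
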