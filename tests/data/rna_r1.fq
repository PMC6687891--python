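@r0
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r1
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r2
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r3
ACGTACGTACGTACG
+
IIIIIIIIIIIIIII
@r4
AAAAACCCCCGGGGN
+
IIIIIIIIIIIIIII
@r5
AAAAACCCCCGGGG
+
IIIIIIIIIIIIII
@r6
GGGGGTTTTTAAAAA
+
IIIIIIIIIIIIIII
@r7
TTTTTGGGGGCCCCC
+
IIIIIIIIIIIIIII
@r8
ACGTACGTACGTACG
+
IIIIIIIIIIIIIII
@r9
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r10
ACGTACGTACGTACG
+
IIIIIIIIIIIIIII
@r11
TTTTTGGGGGCCCCC
+
IIIIIIIIIIIIIII
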