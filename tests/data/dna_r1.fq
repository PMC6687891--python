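@r0
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r1
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r2
ACGTACGTACGTACG
+
IIIIIIIIIIIIIII
@r3
ACGTACGTACGTACG
+
IIIIIIIIIIIIIII
@r4
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r5
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r6
GGGGGTTTTTAAAAA
+
IIIIIIIIIIIIIII
@r7
AAAAACCCCCGGGGG
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
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r12
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
@r13
ACGTACGTACGTACG
+
IIIIIIIIIIIIIII
@r14
AAAAACCCCCGGGG
+
IIIIIIIIIIIIII
@r15
AAAAACCCCCGGGGN
+
IIIIIIIIIIIIIII
@r16
GGGGGTTTTTAAAAA
+
IIIIIIIIIIIIIII
@r17
AAAAACCCCCGGGGG
+
IIIIIIIIIIIIIII
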