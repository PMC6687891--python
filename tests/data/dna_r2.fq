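@r0
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r1
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r2
CGTACGTACGTACGT
+
IIIIIIIIIIIIIII
@r3
CGTACGTACGTACGT
+
IIIIIIIIIIIIIII
@r4
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r5
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r6
TTTTTAAAAACCCCC
+
IIIIIIIIIIIIIII
@r7
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r8
GGGGGGGGGGGGGGG
+
IIIIIIIIIIIIIII
@r9
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r10
CGTACGTACGTACGT
+
IIIIIIIIIIIIIII
@r11
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r12
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r13
CGTACGTACGTACGT
+
IIIIIIIIIIIIIII
@r14
CCCCGGGGGTTTTT
+
IIIIIIIIIIIIII
@r15
NCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r16
TTTTTAAAAACCCCC
+
IIIIIIIIIIIIIII
@r17
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
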