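@r0
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r1
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r2
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r3
CGTACGTACGTACGT
+
IIIIIIIIIIIIIII
@r4
NCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r5
CCCCGGGGGTTTTT
+
IIIIIIIIIIIIII
@r6
TTTTTAAAAACCCCC
+
IIIIIIIIIIIIIII
@r7
GGGGGCCCCCAAAAA
+
IIIIIIIIIIIIIII
@r8
CGTACGTACGTACGT
+
IIIIIIIIIIIIIII
@r9
CCCCCGGGGGTTTTT
+
IIIIIIIIIIIIIII
@r10
TTTTTTTTTTTTTTT
+
IIIIIIIIIIIIIII
@r11
GGGGGCCCCCAAAAA
+
IIIIIIIIIIIIIII
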