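@r0
AAAAAAACGT
+
IIIIIIIIII
@r1
AAAAACAAGT
+
IIIIIIIIII
@r2
AAAAAACAGT
+
IIIIIIIIII
@r3
AAAAAACAGT
+
IIIIIIIIII
@r4
NAAAAAAAAA
+
IIIIIIIIII
@r5
AAAAAAAAA
+
IIIIIIIII
@r6
AAAACAACGT
+
IIIIIIIIII
@r7
AAAAACACGT
+
IIIIIIIIII
@r8
AAAACACAGT
+
IIIIIIIIII
@r9
AAAAACCAGT
+
IIIIIIIIII
@r10
AAAACACCGT
+
IIIIIIIIII
@r11
AAAAACCAGT
+
IIIIIIIIII
@r12
AAAAACCCGT
+
IIIIIIIIII
@r13
AAAACCAAGT
+
IIIIIIIIII
@r14
AAAACCACGT
+
IIIIIIIIII
@r15
AAAACCCAGT
+
IIIIIIIIII
@r16
AAAACCCCGT
+
IIIIIIIIII
@r17
AAAACAAAGT
+
IIIIIIIIII
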