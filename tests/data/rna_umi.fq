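@r0
AAAAAAACGT
+
IIIIIIIIII
@r1
AAAAAAACGT
+
IIIIIIIIII
@r2
AAAAAACAGT
+
IIIIIIIIII
@r3
AAAAAAACGT
+
IIIIIIIIII
@r4
AAAAAACCGT
+
IIIIIIIIII
@r5
AAAAACAAGT
+
IIIIIIIIII
@r6
AAAAACACGT
+
IIIIIIIIII
@r7
AAAAACCAGT
+
IIIIIIIIII
@r8
AAAAACCCGT
+
IIIIIIIIII
@r9
AAAAAACCGT
+
IIIIIIIIII
@r10
AAAACAAAGT
+
IIIIIIIIII
@r11
AAAAACCAGT
+
IIIIIIIIII
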