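# Intron-insertion pattern registry for the bHLH domain, in consensus-column
# coordinates. Anchors are the conserved residues Arg-11, Phe-21, Lys-33 and
# Leu-50; a site is (anchor_column, splice phase). Pattern k carries no
# in-domain intron. Relations: f = a without its first site; e = a without
# its second; c = e plus a site at Leu-50.
label	anchor_column	phase
a	11	0
a	33	0
c	11	0
c	50	0
e	11	0
f	33	0
h	21	1
h	33	0
i	21	1
j	25	1
j	44	2
k	-	-
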