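context	child_sex	child	mother	father	category
autosomal	female	0	0	0	none
autosomal	female	0	0	1	none
autosomal	female	0	0	2	none
autosomal	female	0	1	0	none
autosomal	female	0	1	1	none
autosomal	female	0	1	2	none
autosomal	female	0	2	0	none
autosomal	female	0	2	1	none
autosomal	female	0	2	2	none
autosomal	female	1	0	0	hetero_gain
autosomal	female	1	0	1	none
autosomal	female	1	0	2	none
autosomal	female	1	1	0	none
autosomal	female	1	1	1	none
autosomal	female	1	1	2	none
autosomal	female	1	2	0	none
autosomal	female	1	2	1	none
autosomal	female	1	2	2	none
autosomal	female	2	0	0	homo_gain
autosomal	female	2	0	1	homo_gain
autosomal	female	2	0	2	homo_gain
autosomal	female	2	1	0	homo_gain
autosomal	female	2	1	1	homo_inherit
autosomal	female	2	1	2	none
autosomal	female	2	2	0	homo_gain
autosomal	female	2	2	1	none
autosomal	female	2	2	2	none
x_nonpar	male	0	0	0	none
x_nonpar	male	0	1	0	none
x_nonpar	male	0	2	0	none
x_nonpar	male	1	0	0	homo_gain
x_nonpar	male	1	1	0	homo_inherit
x_nonpar	male	1	2	0	homo_inherit
x_nonpar	male	2	0	0	homo_gain
x_nonpar	male	2	1	0	homo_inherit
x_nonpar	male	2	2	0	homo_inherit
x_nonpar	male	2	0	1	homo_gain
x_nonpar	male	2	1	2	homo_inherit
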