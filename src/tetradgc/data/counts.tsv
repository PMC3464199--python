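label	chromosome	n_31	n_tetrads	n_13	n_40	n_04	genome_panel
567-GC1	1	17	148886				1
3282-GC1	1	17	150910				1
3411-GC1	2	30	150706				1
1369-GC1	3	16	155280				1
424-GC1	4	79	147848				1
1273-GC1	5	14	150429				1
1659-GC1	5	13	149965				1
1369-GC2	3	16	150916				0
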