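allele_name	chromosome	transgene_position	fluorophore	mutation	aa_change
567-GC1	1	3905441	yfp	G95A	G32D
567-GC2	1	3905441	yfp		
567-GC3	1	3905441	yfp		
3282-GC1	1	25652977	amcyan	G118A	G40R
3282-GC2	1	25652977	amcyan	C224T	T75I
3282-GC3	1	25652977	amcyan	G383A	G128E
3282-GC4	1	25652977	amcyan	G118A	G40R
3411-GC1	2	18957093	yfp	G203A	G68D
1369-GC1	3	6472617	dsred	G308A	G103D
1369-GC2	3	6472617	dsred	G428A	W143X
424-GC1	4	1365848	yfp	G174A	W58X
424-GC2	4	1365848	yfp	C188T	T63I
424-GC3	4	1365848	yfp	C617T	S206F
424-GC4	4	1365848	yfp	C332T	A11V
1273-GC1	5	18164269	dsred	G92A	G31D
1273-GC2	5	18164269	dsred	C223T	H75Y
1659-GC1	5	23080567	yfp	G383A	G128D
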