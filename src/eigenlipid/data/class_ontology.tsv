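class	headgroup_category	has_phosphorus	is_chloroplast	is_betaine
PC	phospholipid	1	0	0
PG	phospholipid	1	1	0
PE	phospholipid	1	0	0
SQDG	glycolipid	0	1	0
MGDG	glycolipid	0	1	0
DGDG	glycolipid	0	1	0
GADG	glycolipid	0	0	0
DGTS/A	betaine	0	0	1
DGCC	betaine	0	0	1
TAG	neutral	0	0	0
DAG	neutral	0	0	0
WE	neutral	0	0	0
OL	aminolipid	0	0	0
other	other	0	0	0
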