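; Bundled valence word list for the default sentiment scorer:
; word<TAB>valence in [-1, 1]. The grid covers [-0.9, 0.9] in 0.1 steps so
; the synthetic generator can encode any target polarity to within 0.05.
horrific	-0.9
atrocious	-0.9
terrible	-0.8
awful	-0.8
horrible	-0.7
dreadful	-0.7
miserable	-0.6
nasty	-0.6
bad	-0.5
unpleasant	-0.5
disappointing	-0.4
lousy	-0.4
annoying	-0.3
mediocre	-0.3
dull	-0.2
bland	-0.2
iffy	-0.1
shaky	-0.1
ordinary	0.0
everyday	0.0
fine	0.1
okayish	0.1
decent	0.2
passable	0.2
nice	0.3
solid	0.3
pleasant	0.4
enjoyable	0.4
good	0.5
delightful	0.5
lovely	0.6
impressive	0.6
great	0.7
wonderful	0.7
excellent	0.8
amazing	0.8
fantastic	0.9
superb	0.9
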