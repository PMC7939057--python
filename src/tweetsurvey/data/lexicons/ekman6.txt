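; Bundled emotion word list for the six-basic-emotions model:
; label<TAB>word.
anger	angry
anger	furious
anger	outraged
anger	enraged
anger	irate
disgust	disgusted
disgust	revolting
disgust	repulsive
disgust	sickening
disgust	gross
fear	afraid
fear	scared
fear	terrified
fear	fearful
fear	frightened
fear	panicking
joy	happy
joy	joyful
joy	delighted
joy	cheerful
joy	gleeful
sadness	sad
sadness	sorrowful
sadness	mournful
sadness	grieving
sadness	heartbroken
surprise	surprised
surprise	astonished
surprise	astounded
surprise	startled
surprise	stunned
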