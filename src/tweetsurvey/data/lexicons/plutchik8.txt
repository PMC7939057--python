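; Bundled emotion word list for the eight-primary-emotions (emotion wheel)
; model: label<TAB>word. The six shared labels reuse the basic-emotions
; words.
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
trust	trusting
trust	trustworthy
trust	faithful
trust	dependable
trust	loyal
anticipation	eager
anticipation	expectant
anticipation	anticipating
anticipation	hopeful
anticipation	awaiting
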