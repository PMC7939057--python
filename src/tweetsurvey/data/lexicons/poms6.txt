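; Bundled emotion word list for the six mood states (Profile of Mood
; States) model: label<TAB>word.
anger	angry
anger	furious
anger	irate
anger	resentful
anger	hostile
depression	depressed
depression	dejected
depression	hopeless
depression	gloomy
depression	despairing
depression	downhearted
fatigue	tired
fatigue	exhausted
fatigue	weary
fatigue	fatigued
fatigue	sluggish
vigor	energetic
vigor	lively
vigor	vigorous
vigor	peppy
vigor	spirited
tension	tense
tension	nervous
tension	jittery
tension	uneasy
tension	restless
confusion	confused
confusion	bewildered
confusion	muddled
confusion	perplexed
confusion	dazed
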