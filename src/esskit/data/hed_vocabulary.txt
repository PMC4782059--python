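# Trimmed HED 2.0-style vocabulary snapshot shipped with esskit.
# One node per line; leading tab count = depth; attribute flags in brackets.
Event
	Category
		Experimental stimulus
		Participant response
		Experiment control
		Miscellaneous
	Label [takesValue]
	Description [takesValue]
	Duration [takesValue]
Item
	Object [extensionAllowed]
	Sound [extensionAllowed]
	Symbolic [extensionAllowed]
Sensory Presentation
	Auditory [extensionAllowed]
		Ding
		Buzz
		Tone
	Visual [extensionAllowed]
		Checkerboard
	Tactile [extensionAllowed]
Participant
	ID [takesValue]
	Effect
		Auditory
		Visual
		Tactile
		Cognitive
			Expected
				Standard
				Distractor
			Oddball
				Target
			Penalty
			Reward
			Feedback
	Response
		Button press [extensionAllowed]
		Saccade
Action
	Type [extensionAllowed]
	Button press
Attribute [extensionAllowed]
	Onset
	Offset
	Repetition [takesValue]
Paradigm [extensionAllowed]
	Oddball discrimination paradigm
	Rapid Serial Visual Presentation
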