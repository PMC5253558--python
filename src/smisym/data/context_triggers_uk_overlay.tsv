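# British-English overlay trigger table; OFF by default.
# The base table keeps to the published US-English term lists; UK clinical
# dialect ("nil ...", "denies any ...") goes here so the two configurations
# can be compared explicitly.
phrase	property	direction	action
nil	negation	forward	set
nil evidence of	negation	forward	set
denies any	negation	forward	set
not evident	negation	backward	set
not apparent	negation	backward	set
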