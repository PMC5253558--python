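# Base contextual-property trigger table (ConText/NegEx-style term lists).
# Columns: phrase (token sequence, trailing * = prefix match),
#          property (negation/pseudo_negation/experiencer/historical/hypothetical),
#          direction (forward/backward/both), action (set/terminate).
# Pseudo-negation rows never set anything: they exist so that longer pseudo
# phrases consume tokens that would otherwise fire a negation trigger.
# Termination terms cut a trigger's scope for the listed property.
# The hypothetical set includes screening/indication phrasing ("examined the
# patient for ...") so that examination-for-a-symptom statements are flagged
# as irrelevant rather than affirmed.
phrase	property	direction	action
no	negation	forward	set
not	negation	forward	set
without	negation	forward	set
cannot	negation	forward	set
never	negation	forward	set
denies	negation	forward	set
denied	negation	forward	set
deny	negation	forward	set
free of	negation	forward	set
absence of	negation	forward	set
no evidence of	negation	forward	set
no evidence	negation	forward	set
no sign of	negation	forward	set
no signs of	negation	forward	set
no suggestion of	negation	forward	set
no complaints of	negation	forward	set
negative for	negation	forward	set
fails to reveal	negation	forward	set
never had	negation	forward	set
never developed	negation	forward	set
did not	negation	forward	set
does not	negation	forward	set
unlikely	negation	backward	set
was ruled out	negation	backward	set
is ruled out	negation	backward	set
are ruled out	negation	backward	set
has been ruled out	negation	backward	set
have been ruled out	negation	backward	set
not elicited	negation	backward	set
was denied	negation	backward	set
was absent	negation	backward	set
were absent	negation	backward	set
no increase	pseudo_negation	forward	set
no change	pseudo_negation	forward	set
no definite change	pseudo_negation	forward	set
no significant change	pseudo_negation	forward	set
not cause	pseudo_negation	forward	set
not certain if	pseudo_negation	forward	set
not certain whether	pseudo_negation	forward	set
not necessarily	pseudo_negation	forward	set
not only	pseudo_negation	forward	set
not rule out	pseudo_negation	forward	set
not ruled out	pseudo_negation	forward	set
without difficulty	pseudo_negation	forward	set
gram negative	pseudo_negation	forward	set
no further	pseudo_negation	forward	set
mother	experiencer	forward	set
father	experiencer	forward	set
brother	experiencer	forward	set
sister	experiencer	forward	set
son	experiencer	forward	set
daughter	experiencer	forward	set
wife	experiencer	forward	set
husband	experiencer	forward	set
partner	experiencer	forward	set
aunt	experiencer	forward	set
uncle	experiencer	forward	set
grandmother	experiencer	forward	set
grandfather	experiencer	forward	set
family history	experiencer	forward	set
family member	experiencer	forward	set
relative*	experiencer	forward	set
history of	historical	forward	set
past history of	historical	forward	set
past medical history	historical	forward	set
previous	historical	forward	set
previously	historical	both	set
in the past	historical	backward	set
years ago	historical	backward	set
if	hypothetical	forward	set
return if	hypothetical	forward	set
come back if	hypothetical	forward	set
as needed	hypothetical	forward	set
in case of	hypothetical	forward	set
should	hypothetical	forward	set
monitor for	hypothetical	forward	set
watch for	hypothetical	forward	set
screen for	hypothetical	forward	set
screening for	hypothetical	forward	set
screened for	hypothetical	forward	set
check for	hypothetical	forward	set
checked for	hypothetical	forward	set
test for	hypothetical	forward	set
tested for	hypothetical	forward	set
assess for	hypothetical	forward	set
assessed for	hypothetical	forward	set
evaluate for	hypothetical	forward	set
evaluated for	hypothetical	forward	set
examine for	hypothetical	forward	set
examined for	hypothetical	forward	set
examine the patient for	hypothetical	forward	set
examined the patient for	hypothetical	forward	set
look for	hypothetical	forward	set
rule out	hypothetical	forward	set
r/o	hypothetical	forward	set
to exclude	hypothetical	forward	set
but	negation	forward	terminate
however	negation	forward	terminate
although	negation	forward	terminate
apart from	negation	forward	terminate
aside from	negation	forward	terminate
except	negation	forward	terminate
but	experiencer	forward	terminate
however	experiencer	forward	terminate
although	experiencer	forward	terminate
apart from	experiencer	forward	terminate
aside from	experiencer	forward	terminate
except	experiencer	forward	terminate
but	historical	forward	terminate
however	historical	forward	terminate
although	historical	forward	terminate
apart from	historical	forward	terminate
aside from	historical	forward	terminate
except	historical	forward	terminate
but	hypothetical	forward	terminate
however	hypothetical	forward	terminate
although	hypothetical	forward	terminate
apart from	hypothetical	forward	terminate
aside from	hypothetical	forward	terminate
except	hypothetical	forward	terminate
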