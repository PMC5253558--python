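# SMI symptom lexicon — curated edition.
# Differs from the verbatim edition only where the published worked examples
# contradict the keyword table: "hallucinat*" (vs "hallucinate*") and
# "flight of idea*" (vs "flight of idea").
# Columns: concept, keywords (|-separated phrases, trailing * = prefix match),
# modifiers (|-separated, may be empty), modifier_mode (none/optional/mandatory),
# snomed_ids (comma-separated SCTIDs, may be empty), domain, status.
# Domains for the four excluded concepts and for catatonic syndrome are
# editorial assignments (not part of the published symptom groupings).
concept	keywords	modifiers	modifier_mode	snomed_ids	domain	status
Aggression	aggress*		none	61372001	positive	ml_model
Agitation	agitat*		none	106126000	positive	ml_model
Anhedonia	anhedon*		none	28669007	negative	ml_model
Apathy	apath*		none	20602000	negative	ml_model
Arousal	arous*		none		positive	ml_model
Blunted or flat affect	affect	blunt*|flat*|restrict*	optional	6140007,932006,39370001	negative	ml_model
Catalepsy	catalep*		none	247917007	catatonic	hand_annotate
Catatonic syndrome	catatoni*		none	247917007	catatonic	ml_model
Circumstantial speech	circumstan*		none	18343006	disorganisation	ml_model
Deficient abstract thinking	concrete		none	71573006	negative	ml_model
Delusions	delusion*		none	2073000	positive	ml_model
Derailment of speech	derail*		none	65135009	disorganisation	ml_model
Diminished eye contact	eye contact		none	412786000	negative	ml_model
Disturbed sleep	sleep	not|poor*|interrupt*|nightmare*|disturb*|inadequat*|disorder*|prevent*|stop*|problem*|difficult*|reduced*|less*|impair*|erratic*|unable*|worse*|depriv*	optional	26677001	manic	ml_model
Echolalia	echolalia		none	64712007	catatonic	ml_model
Echopraxia	echopraxia		none	33184005	catatonic	hand_annotate
Elation	elat*		none	34822003	manic	ml_model
Elevated mood	mood	elevat*	mandatory	81548002	manic	ml_model
Emotional withdrawal	withdraw*		none	247755007	negative	ml_model
Euphoria	euphor*		none	85949006	manic	ml_model
Flight of ideas	flight of idea*		none	28810003	disorganisation	ml_model
Formal thought disorder	ftd|thought disorder		none	41591006	disorganisation	ml_model
Grandiosity	grandios*		none	247783009	manic	ml_model
Hallucinations	hallucinat*	audit*|visual*|olfact*|tactil*|third person|first person|3rd person|1st person	optional	45150006,64269007,39672001,66609003,277533007	positive	ml_model
Hostility	hostil*		none	79351003	positive	ml_model
Immobility	immobil*		none	404975000	catatonic	ml_model
Insomnia	insom*		none	193462001	manic	ml_model
Irritability	irritabl*		none	55929007	manic	ml_model
Loosening of associations	associat*		none	55346003	disorganisation	excluded
Loss of coherence	coheren*		none	284596004	disorganisation	ml_model
Low mood	mood		none	366979004	manic	excluded
Mannerisms	mannerism*		none	248026005	catatonic	ml_model
Mutism	mute|mutism		none	88052002	catatonic	keyword_only
Negative syndrome	negative symptom*		none		negative	ml_model
Paranoia	paranoi*		none	191667009	positive	ml_model
Persecutory ideation	persecu*		none	216004	positive	ml_model
Perseverance	persever*		none	44515000	catatonic	ml_model
Poor motivation	motivat*		none	26413003	negative	excluded
Poor rapport	rapport		none	710497003	negative	ml_model
Posturing	postur*		none	271694000	catatonic	ml_model
Poverty of speech	speech*	poverty*|impoverish*	mandatory	72123004	negative	ml_model
Poverty of thought	poverty of thought		none	56435009	negative	ml_model
Pressured speech	speech*	pressure*	mandatory	53890003	manic	ml_model
Rigidity	rigid*		none	311535006	catatonic	ml_model
Social withdrawal	withdraw*	social*	mandatory	105411000	negative	ml_model
Stereotypy	stereotyp*		none	84328007	catatonic	excluded
Stupor	stupor*		none	89458003	catatonic	ml_model
Tangential speech	tangent*		none	74396008	disorganisation	ml_model
Thought block	though* block		none	2899008	disorganisation	ml_model
Waxy flexibility	waxy		none	13052006	catatonic	ml_model
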