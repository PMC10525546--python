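# Baseline keyword -> discursive-repertoire lexicon (Italian cue words).
# A transparent, deterministic stand-in for expert annotation: one rule
# firing per sentence per cue.  It does not and cannot reproduce expert
# coding accuracy; it exists so the pipeline can be exercised end to end.
propongo: Proposal
proposta: Proposal
descrivo: Description
prevedo: Prediction
previsione: Prediction
giudico: Judgement
vergogna: Judgement
commento: Comment
secondo me: Opinion
bisogna: Prescription
obbligo: Prescription
potrebbe: Possibility
forse: Possibility
valuto: Evaluation
confermo: Confirmation
tutti sanno: Generalization
la colpa: Delegating to others
tocca al governo: Delegating to others
è così e basta: Certify Reality
non è vero niente: Certify Reality
invece: Contraposition
perché io: Justification
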