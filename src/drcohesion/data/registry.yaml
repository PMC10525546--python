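# Default dialogic-weight registry: the 23 discursive repertoires (DRs) of
# dialogic science with their printed dialogic weights (dW, 0-20 scale).
# Variable x = "anticipation of future scenarios" (9 DRs);
# variable y = "shared management" (14 DRs).
# Typology (generative / stabilization / hybrid) is unpublished for most DRs
# and therefore left "unknown"; it is metadata only and never alters dW.
repertoires:
  # variable x - anticipation of future scenarios
  - {name: Cause of Action, variable: x, dw: 1.74}
  - {name: Prediction, variable: x, dw: 3.48}
  - {name: Confirmation, variable: x, dw: 5.22}
  - {name: Generalization, variable: x, dw: 6.96}
  - {name: Specification, variable: x, dw: 8.7}
  - {name: Implication, variable: x, dw: 10.44}
  - {name: Consideration, variable: x, dw: 12.18}
  - {name: Anticipation, variable: x, dw: 19.14}
  - {name: Description, variable: x, dw: 20}
  # variable y - shared management
  - {name: Certify Reality, variable: y, dw: 0.87}
  - {name: Contraposition, variable: y, dw: 2.61}
  - {name: Judgement, variable: y, dw: 4.35}
  - {name: Non answer, variable: y, dw: 6.09}
  - {name: Justification, variable: y, dw: 7.83}
  - {name: Delegating to others, variable: y, dw: 9.57}
  - {name: Evaluation, variable: y, dw: 11.31}
  - {name: Opinion, variable: y, dw: 13.05}
  - {name: Declaration of Aim, variable: y, dw: 13.92}
  - {name: Prescription, variable: y, dw: 14.79}
  - {name: Comment, variable: y, dw: 15.66}
  - {name: Reshaping, variable: y, dw: 16.53}
  - {name: Possibility, variable: y, dw: 17.4}
  - {name: Proposal, variable: y, dw: 18.27}
# Spelling variants used in published frequency tables, mapped to the
# canonical names above so frequencies join to weights.
aliases:
  Deresponsibility: Delegating to others
  Prevision: Prediction
  Generalisation: Generalization
  Declaration of aims: Declaration of Aim
  Cause of action: Cause of Action
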