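"""Precision-first model selection with a recall floor.

For information-extraction pipelines a false entity poisons every
downstream step, while marginal recall gains above a floor buy little.
Selection therefore picks, among candidates with development recall
strictly above 85%, the one with the highest precision.
"""

from chemner.evalsel import Candidate, select_model

candidates = [
    Candidate("fine-tuned encoder",        precision=89.9, recall=86.9),
    Candidate("legacy tokenizer baseline", precision=86.6, recall=82.8),
    Candidate("frozen embeddings",         precision=86.9, recall=90.3),
    Candidate("frozen + char-CNN",         precision=88.7, recall=90.7),
]

print("candidate                     P      R")
for c in candidates:
    print(f"{c.config:<28}{c.precision:5.1f}  {c.recall:5.1f}")

chosen = select_model(candidates, recall_floor=85.0)
print(f"\nselected: {chosen}")
print("the 82.8-recall baseline is excluded by the floor; among the rest the")
print("fine-tuned encoder wins on precision despite not having the best F1.")
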