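"""Filter back-splice junction candidates and type the surviving circRNAs.

Seven conjunctive conditions (single breakpoint, small anchor overlap and
edit distance, enough unique reads overall and per-sample-majority, one
good anchor quality, span under 100 kb) separate credible back-splice
junctions from alignment artifacts; survivors are classified into six
positional types against the annotation.
"""

from cerna_forge import generate_dataset
from cerna_forge.circrna import classify_all, evaluate_conditions, filter_candidates
from cerna_forge.synthetic import generate_circ_candidates

# a constructed table: 6 good junctions, 8 each violating one condition
table = generate_circ_candidates(n_pass=6, n_fail=8, seed=4)
checks = evaluate_conditions(table, n_samples=9)
kept = filter_candidates(table, n_samples=9)
print(f"retained {len(kept)} of {len(table)} candidates")
print("rejection reasons:", checks.loc[~checks.pass_all, "fail_reason"].tolist())

# classification against a real annotation
ds = generate_dataset(seed=1)
records = classify_all(filter_candidates(ds.circ_candidates, 9), ds.annotation)
print("\ncircRNA types (each junction gets exactly one of six labels):")
print(records["circ_type"].value_counts().to_string())
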