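"""Two decision-support analyses on top of the predictions:

1. mechanism inference — cohort drug pairs whose gold-standard record
   is the unspecific adverse-effect type 26 and for which the model
   co-predicts another type that may explain it;
2. substitution — for pairs flagged with a critical interaction type,
   approved drugs with the identical (target, action) set whose
   candidate pair keeps every critical activation below 0.47.
"""

from ddiscreen import load_templates, render_sentence, run_study

study = run_study()
templates = load_templates()
names = {r.drug_id: r.name for r in study.scenario.registry}

print(f"mechanism candidates: {len(study.mechanism_candidates)}")
for cand in study.mechanism_candidates[:2]:
    print("\n  gold:      " + render_sentence(cand.gold_record, templates, names))
    for m in cand.mechanisms:
        print(f"  mechanism: {render_sentence(m, templates, names)} "
              f"(score {m.score:.3f})")

n_flagged = len(study.flagged_pairs)
n_preventable = sum(1 for v in study.substitutions.values() if v)
print(f"\ncritical pairs flagged in the cohort: {n_flagged}")
print(f"preventable by substitution:          {n_preventable} "
      f"({n_preventable / n_flagged:.1%})")

example = next(s for subs in study.substitutions.values() for s in subs)
a, b = example.original_pair
print(f"\nexample: pair ({names[a]}, {names[b]}) flagged for critical "
      f"type(s) {example.flagged_types};")
print(f"  replacing {names[example.replaced]} with "
      f"{names[example.alternative]} keeps every critical activation at "
      f"{example.max_critical_activation:.3f} < 0.47 in both orderings.")
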