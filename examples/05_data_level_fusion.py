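"""Data-level fusion: one entropy-profile library, leave-one-out K=2.

Generates a 16-case cohort, fuses each recording's five channels into a
nine-scale entropy profile, and evaluates the profile library leave-one-out.
A query is counted correct when its class appears among the two retrieved
cases; the confusion matrix uses the top-1 prediction (Stressed positive).
"""

from physiofuse import SimulationSpec, generate_library, leave_one_out, metrics

spec = SimulationSpec(seed=1, complexity_gap=0.8)
lib = generate_library(spec, mode="data")
report = leave_one_out(lib)

print(report.render_text())
m = metrics(report.confusion)
print(f"\nWith a strong complexity gap the profiles separate the classes "
      f"completely (accuracy {m['accuracy'] * 100:.1f}%); at gap 0 the same "
      f"pipeline stays at chance level.")
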