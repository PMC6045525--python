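"""Choose the number of latent classes with the G2-based criteria.

Candidate models with 2-4 classes are fitted to one simulated dataset.
A larger model is accepted when both the G2-based AIC and BIC drop by at
least 5%, or when the current model fails the goodness-of-fit test
(p <= 0.05) while the larger one passes.
"""

import painlca as pl

fixture = pl.load_fixture("table2")
data = pl.simulate(fixture, pl.GeneratorConfig(n_total=1611, seed=7))

report = pl.select_classes(data, c_min=2, c_max=4,
                           config=pl.EMConfig(seed=11, n_starts=20))

print(f"{'C':>2} {'G2':>8} {'df':>3} {'GOF p':>7} {'AIC':>8} {'BIC':>8}")
for row in report.criteria_table():
    mark = "  <- selected" if row["selected"] else ""
    p = "-" if row["gof_p"] is None else f"{row['gof_p']:.3f}"
    print(f"{row['n_classes']:>2} {row['gsq']:>8.2f} {row['df']:>3} {p:>7} "
          f"{row['aic']:>8.2f} {row['bic']:>8.2f}{mark}")

print("\ndecision trace:")
for step in report.rule_trace:
    print(f"  C={step['n_classes']}: {step.get('action', '')}")
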