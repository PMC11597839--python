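"""Screen the packaged panel against Lipinski, Ghose and Veber rules.

Uses the experimentally determined logP_TLC as the lipophilicity input and
prints the per-compound verdicts plus the ESOL solubility estimate for one
representative compound.
"""

from chromlip import (
    descriptor_sheet,
    esol_logs,
    experimental_logp_inputs,
    load_triazole_panel,
    screen,
    solubility_band,
)

descs = descriptor_sheet(load_triazole_panel(), logp_inputs=experimental_logp_inputs())
report = screen(descs)
summary = report.pivot(index="compound_id", columns="rule", values="passed")
print(summary.to_string())
n_pass = int(report.groupby("compound_id")["passed"].all().sum())
print(f"\n{n_pass}/{len(descs)} compounds pass all three rules in strict mode.")

d2a = next(d for d in descs if d.compound_id == "2a")
logs = esol_logs(d2a)
print(f"\nESOL for 2a (logP_TLC input): log S = {logs:.2f} mol/L "
      f"-> '{solubility_band(logs)}' band")
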