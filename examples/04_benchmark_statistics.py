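"""Benchmark statistics of the packaged CB[8] host-guest reference set.

Recomputes signed deviations from experiment for ten drug-like guests,
their MAE/RMSE, the overbinding count, and the mean differences between
DFT association-energy methods.
"""

from crebind import (
    deviations,
    error_summary,
    method_mean_difference,
    overbinding_count,
)
from crebind.datasets import load_association_reference, load_binding_reference

rows = load_binding_reference()
for flavor in ("top", "ensemble"):
    dev = deviations(rows, flavor)
    summ = error_summary(dev)
    print(f"{flavor:>8s}: MAE {summ.mae:.2f}  RMSE {summ.rmse:.2f} kcal/mol, "
          f"{overbinding_count(dev)}/{summ.n} complexes overbind")

assoc = load_association_reference()
for a, b in (("B2PLYP", "PBE0"), ("PWPB95", "PBE0"), ("GFN2-xTB", "PBE0")):
    d = method_mean_difference(assoc, a, b)
    print(f"mean E_a({a}) - E_a({b}) = {d:+.2f} kcal/mol")
print("(negative means the first method binds more strongly on average)")
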