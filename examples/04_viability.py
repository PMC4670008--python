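"""Stage-binned lethality: where in development do embryos fail, by condition?

Each unhatched embryo is binned by its last recorded landmark: before
gastrulation completes, between gastrulation and the heart-shaped midgut,
late pre-tracheal development, or after tracheal filling (hatching failure).
"""

import oxyscale as ox

dataset = ox.generate_dataset(ox.default_config(n_per_condition=50, noise_sd=0.5, seed=3))
table = ox.lethality_table(dataset)

print("fate fractions at 27.5 C:")
header = ["O2%"] + [b.value.replace("_failure", "") for b in ox.FATE_BINS]
print("  " + "  ".join(f"{h:>24s}" if i else f"{h:>4s}" for i, h in enumerate(header)))
for o2 in (10.0, 14.0, 17.0, 21.0, 25.0, 29.0):
    fr = table.fractions(ox.Condition(o2, 27.5))
    cells = "  ".join(f"{fr[b]:24.2f}" for b in ox.FATE_BINS)
    print(f"  {o2:4.0f}  {cells}")
# Hypoxia shifts failure into mid-embryogenesis (germ-band retraction region),
# mild hypoxia leaves many embryos unable to hatch, hyperoxia pushes failure
# before gastrulation, and survival peaks at 25% rather than atmospheric 21%.
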