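"""Date lineage splits from mean synonymous divergence.

Under a strict molecular clock, T = Ks / (2r): synonymous substitutions
accumulate on both lineages at rate r per site per year. The default
rate (6.5e-9) is a standard grass value; the mean-Ks inputs below are
illustrative values on the scale seen for oat against wheat-lineage
diploids (~0.37) through maize (~0.85).
"""

from bgcpipe import divergence_time

for label, mean_ks in [
    ("wheat-lineage diploid", 0.3705),
    ("barley-like", 0.4043),
    ("rice-like", 0.6877),
    ("maize-like", 0.8463),
]:
    est = divergence_time(mean_ks)
    print(f"mean Ks = {mean_ks:.4f}  ->  {est.time_years / 1e6:5.1f} My  ({label})")

print("\nrate sensitivity at Ks = 0.3705:")
for rate in (5e-9, 6.5e-9, 8e-9):
    est = divergence_time(0.3705, rate=rate)
    print(f"  r = {rate:.1e}/site/year -> {est.time_years / 1e6:5.1f} My")
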