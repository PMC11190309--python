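"""Fragment-size selection: how the 230 bp cut enriches fetal DNA.

Fetal cfDNA fragments are shorter than maternal ones, so retaining only
fragments below a length threshold shifts the mixture toward the fetus.
"""

import niptcnv as nc
from niptcnv.fragments import DEFAULT_FRAGMENT_MODEL

for thr in (180, 200, 230, 300, 600):
    p_f = nc.retention_probability(DEFAULT_FRAGMENT_MODEL, "fetal", thr)
    p_m = nc.retention_probability(DEFAULT_FRAGMENT_MODEL, "maternal", thr)
    res = nc.enrich_fetal_fraction(0.1376, threshold_bp=thr)
    print(f"threshold {thr:>3} bp: keep {p_f:.3f} fetal / {p_m:.3f} maternal "
          f"-> ff 13.76% becomes {res.output_ff:.2%}")

# At the 230 bp operating point the cohort-mean fetal fraction moves from
# 13.76% to ~18.5%, matching the published pre/post-improvement shift
# (13.76% -> 18.44%).  A lower threshold enriches harder but discards ever
# more library mass; at 600 bp (the whole support) nothing changes.
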