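"""Compare standardized karyotypes across species.

Simulates measurement data for all three reference species, standardizes
each, and compares orthologous (rank-matched) chromosomes: two species share
a chromosome when their Q1-Q3 centromeric-index intervals intersect.
Divergent chromosomes are listed as index runs; grand means of i and length
summarise each species.
"""

import pandas as pd

import karyostd as ks
from karyostd.pipeline import standardize_frame

frames = []
for species in ("CAU", "CCA", "CGI"):
    spec = ks.spec_from_medians(species, ks.reference_medians(species))
    frames.append(ks.generate(spec, seed=11))

result = standardize_frame(pd.concat(frames, ignore_index=True))
comparison = ks.compare_karyotypes(result.summaries)
print(ks.divergence_summary(comparison))
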