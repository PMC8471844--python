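"""Classify the packaged reference medians and print karyotype formulas.

Loads the shipped table of median centromeric indices for the three diploid
Carassius species (50 ranked chromosomes each, 2n = 100), assigns each a
Levan category and prints the diploid karyotype formulas.  Each formula term
is <count><category>: e.g. "24m" means 24 of the 100 chromosomes are
metacentric; the shortened form merges the three terminal-leaning categories
(st, a, T) into one "st-T" count.
"""

import karyostd as ks

for species in ("CAU", "CCA", "CGI"):
    medians = ks.reference_medians(species)
    karyotype = ks.build_karyotype(species, medians)
    print(f"{species}: {karyotype.formula}")
    print(f"     shortened: {karyotype.shortened_formula}")
    print(f"     chr1 median i = {medians[0]:.2f} -> {karyotype.entries[0].category}")
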