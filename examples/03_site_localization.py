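"""Localize a phosphosite from fragment ions with the binomial score.

Builds a spectrum containing the b/y ions of AYAAAAGpYAAK phosphorylated on
the second tyrosine (Y8), then asks the localizer to choose between the two
candidate tyrosines.
"""

import numpy as np

from phosquant.mass_chem import parse_peptide
from phosquant.site_localization import _all_by_ions, _isoform, localize

pep = parse_peptide("AYAAAAGYAAK", charge=2)
true_site = 7  # 0-based -> residue Y8

ions = _all_by_ions(_isoform(pep, true_site))
mz = np.asarray(ions)
intensity = np.full(len(mz), 500.0)

res = localize((mz, intensity), pep, candidate_positions=[1, 7])
print(f"candidates          : Y2, Y8")
print(f"best site           : {pep.sequence[res.best_position]}{res.best_position + 1}")
print(f"localization score  : {res.score:.1f}  (-10*log10 binomial tail difference)")
print(f"ambiguous           : {res.ambiguous}")
print(f"matched ions        : {res.match_counts} at peak depth {res.depth}")
# A high score means the site-determining ions of the winning isoform are
# matched far beyond what random peaks at this depth would explain.
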