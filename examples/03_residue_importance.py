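"""Map specificity-determining residues with RNA queries.

Leave-one-out RNA queries reconstruct, for each protein, the peptide
templates its embedding associates with its measured RNA profile.  After
column standardization across the cohort, summing template values onto the
residues they cover gives a residue importance score (RIS) track.  On the
synthetic cohort the truth is known: the planted 20-residue specificity
block should score above the rest of the RNA-binding region.
"""

import warnings

import numpy as np
from sklearn.metrics import roc_auc_score

from jple import core, ris, synthetic

fixture = synthetic.gen_families(n_families=8, members=4, seed=7)
planted = synthetic.gen_planted_model(fixture, noise_sd=0.0, seed=7)
R = synthetic.gen_profiles(fixture, planted)
P = fixture.peptide_matrix()

reconstructions = core.loocv_rna_queries(P, R)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    std = ris.standardize_reconstructions(ris.ReconstructionSet(reconstructions))

rbr = fixture.rbrs()[0]           # founder of family 0
row = std.matrix.values[0]
track = ris.residue_importance(dict(zip(std.matrix.col_ids, row)), rbr)

b0, b1 = fixture.block_span
labels = []
for seg, start in rbr.segments:
    labels.extend(1 if b0 <= start + k + 1 <= b1 else 0
                  for k in range(len(seg)))
labels = np.array(labels)

auroc = roc_auc_score(labels, track.scores)
print(f"RIS track over a {len(track.scores)}-residue RNA-binding region")
print(f"mean RIS inside planted block:  {track.scores[labels == 1].mean():8.2f}")
print(f"mean RIS outside planted block: {track.scores[labels == 0].mean():8.2f}")
print(f"AUROC for block recovery: {auroc:.3f}")
# An AUROC near 1 means the embedding localized the residues that were, by
# construction, the only determinants of this family's RNA specificity.
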