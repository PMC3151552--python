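"""Power designs reconstructed from the published summary information of
the Netherlands Twin Register genotyped anxious-depression samples.

Only aggregate counts were published: the number of genotyped individuals
per sex, the number of complete MZ pairs among them (each MZ pair carries
one unique genotype), and the number with a score at each survey occasion.
The rosters here reproduce exactly that information set:

* adults — genotyped non-MZ individuals are treated as unrelated
  singletons (the published power analyses likewise considered only the
  number of unique genotypes), MZ pairs as intact pairs sharing one
  genotype;
* children — all genotyped twins belonged to pairs, so the non-MZ
  remainder is laid out as complete same-sex DZ pairs (dosage correlation
  0.5 by Mendelian transmission).

Occasion participation is assigned individual-by-individual at the
published per-occasion rates (every individual keeps at least one
occasion, as in the genotyped samples).  Loadings are the square roots of
the published per-occasion factor-variance fractions; latent twin
correlations are the published ones.
"""

from __future__ import annotations

import numpy as np

from .model import FamilyDesign, Member
from .params import CHILD_INDICATORS, ADULT_OCCASIONS, default_params
from .power import PowerDesign

__all__ = ["adult_reference_design", "child_reference_design"]

#: genotyped adults with >= 1 A/D score, complete MZ pairs among them, and
#: the number scored at each of the five survey occasions
ADULT_COUNTS = {
    "m": {"n": 562, "mz_pairs": 42, "occ": (63, 151, 298, 311, 425)},
    "f": {"n": 942, "mz_pairs": 89, "occ": (114, 246, 519, 603, 751)},
}
#: genotyped children and their per-indicator counts
#: (mot7, fat7, mot10, fat10, mot12, fat12, self)
CHILD_COUNTS = {
    "m": {"n": 526, "mz_pairs": 144, "occ": (479, 414, 468, 399, 438, 367, 364)},
    "f": {"n": 552, "mz_pairs": 160, "occ": (509, 446, 480, 389, 471, 396, 454)},
}


def _draw_pattern(labels, probs, rng) -> tuple[str, ...]:
    while True:
        keep = rng.random(len(labels)) < probs
        if keep.any():
            return tuple(l for l, k in zip(labels, keep) if k)


def _twin_pair(fid: str, sex: str, zyg: str, labels, probs, rng) -> FamilyDesign:
    members = [Member(iid=f"{fid}_T{i+1}", role=f"twin{i+1}", sex=sex,
                      zygosity=zyg, observed=_draw_pattern(labels, probs, rng))
               for i in range(2)]
    return FamilyDesign(fid=fid, cohort="adult" if labels == ADULT_OCCASIONS
                        else "child", members=members)


def adult_reference_design(sex: str, seed: int = 0, alpha: float = 0.01,
                           maf: float = 0.5) -> PowerDesign:
    """Genotyped adult sample of one sex (unique genotypes: 520 male /
    853 female)."""
    rng = np.random.default_rng(seed)
    c = ADULT_COUNTS[sex]
    probs = np.array(c["occ"]) / c["n"]
    labels = ADULT_OCCASIONS
    fams = []
    for k in range(c["mz_pairs"]):
        fams.append((_twin_pair(f"MZ{k:03d}", sex, "MZ", labels, probs, rng), 1.0))
    n_single = c["n"] - 2 * c["mz_pairs"]
    for k in range(n_single):
        m = Member(iid=f"S{k:04d}", role="twin1", sex=sex, zygosity="DZ",
                   observed=_draw_pattern(labels, probs, rng))
        fams.append((FamilyDesign(fid=f"S{k:04d}", cohort="adult",
                                  members=[m]), 1.0))
    return PowerDesign(families=fams, params=default_params("adult"),
                       maf=maf, alpha=alpha, df=1, test_sex=sex)


def child_reference_design(sex: str, seed: int = 0, alpha: float = 0.01,
                           maf: float = 0.5) -> PowerDesign:
    """Genotyped children's sample of one sex (unique genotypes: 382 boys /
    392 girls; all twins, non-MZ laid out as complete DZ pairs)."""
    rng = np.random.default_rng(seed)
    c = CHILD_COUNTS[sex]
    probs = np.array(c["occ"]) / c["n"]
    labels = CHILD_INDICATORS
    fams = []
    for k in range(c["mz_pairs"]):
        fams.append((_twin_pair(f"MZ{k:03d}", sex, "MZ", labels, probs, rng), 1.0))
    n_dz_pairs = (c["n"] - 2 * c["mz_pairs"]) // 2
    for k in range(n_dz_pairs):
        fams.append((_twin_pair(f"DZ{k:03d}", sex, "DZ", labels, probs, rng), 1.0))
    return PowerDesign(families=fams, params=default_params("child"),
                       maf=maf, alpha=alpha, df=1, test_sex=sex)
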