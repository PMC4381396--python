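"""Active-feature enrichment, sensitivity/specificity and randomization Z-scores.

Feature sets:

* ``F_EGFd`` — chemical features of all successfully docked probe compounds;
* ``F_AS``   — the subset that ever docked at the active site;
* ``F_AS_bar`` = ``F_EGFd \\ F_AS`` — features that never docked there;
* ``F_A``    — "active features": features also present in known active
  ligands, ``F_EGFd ∩ features(actives)``.

With |·| the set cardinal,

    E(EGFd)   = |F_A| / |F_EGFd|
    E(AS)     = |F_A ∩ F_AS| / |F_AS|
    E(AS_bar) = |F_A ∩ F_AS_bar| / |F_AS_bar|
    Se        = |F_A ∩ F_AS| / |F_A|
    Sp        = |(F_EGFd \\ F_A) ∩ F_AS_bar| / |F_EGFd \\ F_A|

Significance is assessed by randomizing which features dock at the active
site: F_AS (resp. F_AS_bar) is redrawn uniformly without replacement from
F_EGFd, preserving its size, many times; the Z-score is the distance of the
observed Se (resp. Sp) from the null mean in units of the null sd.  |Z| > 4
is flagged as strongly significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureSets",
    "EnrichmentReport",
    "build_sets",
    "enrichments",
    "sensitivity_specificity",
    "randomization_zscores",
    "enrichment_report",
]

Z_SIGNIFICANCE = 4.0


@dataclass
class FeatureSets:
    f_egfd: frozenset
    f_as: frozenset
    f_as_bar: frozenset
    f_a: frozenset


@dataclass
class EnrichmentReport:
    e_egfd: float
    e_as: float | None
    e_as_bar: float | None
    se: float | None
    sp: float | None
    ratio: float | None               # Se / (1 - Sp); +inf when Sp == 1
    z_se: float | None
    z_sp: float | None
    significant: bool | None
    n_randomizations: int
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "e_egfd", "e_as", "e_as_bar", "se", "sp", "ratio",
            "z_se", "z_sp", "significant", "n_randomizations", "seed")}


def build_sets(docked_features, as_features, active_ligand_features) -> FeatureSets:
    """Assemble the four feature sets from raw id collections."""
    f_egfd = frozenset(docked_features)
    f_as = frozenset(as_features)
    if not f_as <= f_egfd:
        raise ValueError("as_features must be a subset of docked_features")
    return FeatureSets(
        f_egfd=f_egfd,
        f_as=f_as,
        f_as_bar=f_egfd - f_as,
        f_a=f_egfd & frozenset(active_ligand_features),
    )


def enrichments(sets: FeatureSets) -> tuple[float, float | None, float | None]:
    """Active-feature enrichment in the docked library, the active site and
    its complement; undefined denominators are reported as None."""
    if not sets.f_egfd:
        raise ValueError("F_EGFd is empty")
    e_egfd = len(sets.f_a) / len(sets.f_egfd)
    e_as = len(sets.f_a & sets.f_as) / len(sets.f_as) if sets.f_as else None
    e_bar = (len(sets.f_a & sets.f_as_bar) / len(sets.f_as_bar)
             if sets.f_as_bar else None)
    return e_egfd, e_as, e_bar


def sensitivity_specificity(sets: FeatureSets
                            ) -> tuple[float | None, float | None, float | None]:
    """Se, Sp and the likelihood ratio Se/(1−Sp); None where undefined,
    +inf when Sp = 1 with Se > 0."""
    inactive = sets.f_egfd - sets.f_a
    se = len(sets.f_a & sets.f_as) / len(sets.f_a) if sets.f_a else None
    sp = len(inactive & sets.f_as_bar) / len(inactive) if inactive else None
    if se is None or sp is None:
        ratio = None
    elif sp == 1.0:
        ratio = float("inf") if se > 0 else None
    else:
        ratio = se / (1.0 - sp)
    return se, sp, ratio


def _null_overlaps(n_universe: int, n_marked: int, draw_size: int,
                   n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Overlap counts |marked ∩ draw| for uniform draws without replacement.

    Implemented as row permutations of a membership indicator (a genuine
    resampling of feature identities), chunked to bound memory.
    """
    indicator = np.zeros(n_universe, dtype=np.int8)
    indicator[:n_marked] = 1
    out = np.empty(n_draws, dtype=np.int64)
    chunk = max(1, min(n_draws, 20_000_000 // max(n_universe, 1)))
    for s in range(0, n_draws, chunk):
        m = min(chunk, n_draws - s)
        tiled = np.tile(indicator, (m, 1))
        perm = rng.permuted(tiled, axis=1)
        out[s:s + m] = perm[:, :draw_size].sum(axis=1)
    return out


def randomization_zscores(sets: FeatureSets, n_randomizations: int = 1_000_000,
                          seed: int = 0) -> tuple[float | None, float | None]:
    """Z-scores of Se and Sp against nulls that redraw F_AS (resp. F_AS_bar)
    uniformly without replacement from F_EGFd, preserving set sizes."""
    if n_randomizations < 100:
        raise ValueError("n_randomizations must be >= 100")
    rng = np.random.default_rng(seed)
    se, sp, _ = sensitivity_specificity(sets)
    n = len(sets.f_egfd)

    z_se = None
    if se is not None and sets.f_as:
        null = _null_overlaps(n, len(sets.f_a), len(sets.f_as),
                              n_randomizations, rng) / len(sets.f_a)
        sd = null.std()
        z_se = float((se - null.mean()) / sd) if sd > 0 else None

    z_sp = None
    inactive = sets.f_egfd - sets.f_a
    if sp is not None and sets.f_as_bar:
        null = _null_overlaps(n, len(inactive), len(sets.f_as_bar),
                              n_randomizations, rng) / len(inactive)
        sd = null.std()
        z_sp = float((sp - null.mean()) / sd) if sd > 0 else None
    return z_se, z_sp


def enrichment_report(sets: FeatureSets, n_randomizations: int = 1_000_000,
                      seed: int = 0) -> EnrichmentReport:
    """Full enrichment analysis of one target's feature sets."""
    e_egfd, e_as, e_bar = enrichments(sets)
    se, sp, ratio = sensitivity_specificity(sets)
    z_se, z_sp = randomization_zscores(sets, n_randomizations, seed)
    significant = None
    if z_se is not None and z_sp is not None:
        significant = abs(z_se) > Z_SIGNIFICANCE and abs(z_sp) > Z_SIGNIFICANCE
    return EnrichmentReport(e_egfd, e_as, e_bar, se, sp, ratio, z_se, z_sp,
                            significant, n_randomizations, seed)
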