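"""Functional entities, redundancy, trait-space ordination and richness.

The functional composition of an assemblage is summarized through
*functional entities* (FEs): unique combinations of trait states.  Per time
bin the module reports the number of FEs, functional redundancy (mean
species per FE), over-redundancy (percentage of species in FEs filled above
the mean), and functional richness (convex-hull volume in a Gower/PCoA
trait space, as a percentage of the global pool's hull).  Null expectations
come from richness-matched random assembly out of the global species pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .data_io import PresenceMatrix
from .traits import SpeciesTraitTable, TraitScheme

__all__ = [
    "FEAssignment",
    "FunctionalSpace",
    "assign_functional_entities",
    "count_possible_entities",
    "occupancy_percentage",
    "categorize_species_redundancy",
    "REDUNDANCY_CATEGORIES",
    "fe_timeseries_metrics",
    "gower_distance_matrix",
    "build_functional_space",
    "functional_richness_timeseries",
    "null_expectation",
    "fd_timeseries",
    "fd_with_uncertainty",
]

#: Redundancy categories keyed to FE occupancy (number of species sharing
#: the FE): unique = {1}, very_low = {2..3}, low = {4..10}, high = {11..32},
#: very_high = {33..}.  Boundaries follow the verbal species counts of the
#: log10 partition (0, 0.5, 1, 1.5) rounded to whole species.
REDUNDANCY_CATEGORIES = ("unique", "very_low", "low", "high", "very_high")
_CATEGORY_UPPER = (1, 3, 10, 32)  # inclusive upper occupancy per category


@dataclass
class FEAssignment:
    """Functional-entity membership for a species pool."""

    species_ids: list[str]
    fe_index: np.ndarray  # FE id per species
    occupancy: np.ndarray  # species count per FE

    def __post_init__(self) -> None:
        self.fe_index = np.asarray(self.fe_index, dtype=np.int64)
        self.occupancy = np.asarray(self.occupancy, dtype=np.int64)
        if self.occupancy.sum() != len(self.species_ids):
            raise ValueError("occupancies must sum to the number of species")

    @property
    def n_fe(self) -> int:
        return len(self.occupancy)

    @property
    def species_occupancy(self) -> np.ndarray:
        """Occupancy of each species' own FE (species-level redundancy)."""
        return self.occupancy[self.fe_index]

    @property
    def logfr(self) -> np.ndarray:
        """log10 species-level functional redundancy; 0 for unique species."""
        return np.log10(self.species_occupancy)


def assign_functional_entities(traits: SpeciesTraitTable) -> FEAssignment:
    """Group species into FEs (distinct trait-state vectors)."""
    _, inverse, counts = np.unique(
        traits.states, axis=0, return_inverse=True, return_counts=True
    )
    return FEAssignment(
        species_ids=list(traits.species_ids),
        fe_index=inverse.ravel(),
        occupancy=counts,
    )


def count_possible_entities(scheme: TraitScheme) -> int:
    """Total number of trait-state combinations, prod_v N_v."""
    return int(np.prod(scheme.states_per_trait))


def occupancy_percentage(n_occupied: int, scheme: TraitScheme) -> float:
    """Percentage of possible FEs realized by the sample, to two decimals."""
    possible = count_possible_entities(scheme)
    if not 0 <= n_occupied <= possible:
        raise ValueError(
            f"n_occupied must lie in [0, {possible}], got {n_occupied}"
        )
    return round(100.0 * n_occupied / possible, 2)


def categorize_species_redundancy(fe: FEAssignment) -> np.ndarray:
    """Assign each species one of the five redundancy categories from the
    occupancy of its FE (computed over the full species pool)."""
    occ = fe.species_occupancy
    cat = np.searchsorted(np.array(_CATEGORY_UPPER), occ, side="left")
    labels = np.asarray(REDUNDANCY_CATEGORIES, dtype=object)
    return labels[cat]


def _fe_metrics_for_subset(states: np.ndarray) -> tuple[int, float, float]:
    """(n_FE, redundancy, over-redundancy%) for a subset's state matrix."""
    _, counts = np.unique(states, axis=0, return_counts=True)
    s = int(counts.sum())
    n_fe = len(counts)
    redundancy = s / n_fe
    # strictly above the mean: the degenerate single-FE bin scores 0
    over = 100.0 * counts[counts > redundancy].sum() / s
    return n_fe, redundancy, over


def _align_presence_to_traits(
    presence: PresenceMatrix, traits: SpeciesTraitTable
) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(traits.species_ids)}
    missing = [s for s in presence.species_ids if s not in pos]
    if missing:
        raise KeyError(f"species missing from trait table: {missing[:5]}")
    return np.array([pos[s] for s in presence.species_ids], dtype=np.int64)


def fe_timeseries_metrics(
    presence: PresenceMatrix, traits: SpeciesTraitTable
) -> pd.DataFrame:
    """Per-bin FE count, redundancy and over-redundancy.

    FEs are recomputed from each bin's present species.  Empty bins are
    reported with NaN metrics rather than zeros.
    """
    rows = []
    idx = _align_presence_to_traits(presence, traits)
    for b in range(presence.n_bins):
        mask = presence.presence[:, b]
        row = {
            "bin_old": presence.bin_old[b],
            "bin_young": presence.bin_young[b],
            "n_species": int(mask.sum()),
        }
        if mask.any():
            states = traits.states[idx[mask]]
            n_fe, red, over = _fe_metrics_for_subset(states)
            row.update(n_fe=n_fe, redundancy=red, over_redundancy=over)
        else:
            row.update(n_fe=np.nan, redundancy=np.nan, over_redundancy=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def gower_distance_matrix(
    traits: SpeciesTraitTable, scheme: TraitScheme | None = None
) -> np.ndarray:
    """Symmetric Gower dissimilarity between species, in [0, 1].

    Unordered traits contribute a 0/1 mismatch; ordinal traits contribute
    the absolute rank difference normalized by the trait's rank range.
    Trait contributions are averaged with equal weight.
    """
    scheme = scheme or traits.scheme
    S = traits.n_species
    total = np.zeros((S, S))
    for v, trait in enumerate(scheme.traits):
        col = traits.states[:, v].astype(float)
        if trait.ordinal and trait.n_states > 1:
            contrib = np.abs(col[:, None] - col[None, :]) / (trait.n_states - 1)
        elif trait.n_states > 1:
            contrib = (col[:, None] != col[None, :]).astype(float)
        else:
            contrib = np.zeros((S, S))
        total += contrib
    return total / scheme.n_traits


@dataclass
class FunctionalSpace:
    """PCoA embedding of the species pool with quality-of-space scores."""

    species_ids: list[str]
    coordinates: np.ndarray = field(repr=False)  # S x n_axes
    eigenvalues: np.ndarray
    quality: dict[int, float]
    chosen_dim: int
    input_distances: np.ndarray = field(repr=False)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def chosen_coordinates(self) -> np.ndarray:
        return self.coordinates[:, : self.chosen_dim]


def _cailliez_corrected(dist: np.ndarray) -> np.ndarray:
    """Additive (Cailliez) constant making the distance matrix Euclidean."""
    n = dist.shape[0]
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    F1 = -0.5 * J @ d2 @ J
    F2 = -0.5 * J @ dist @ J
    upper = np.block([[np.zeros((n, n)), 2 * F1], [-np.eye(n), -4 * F2]])
    c = float(np.max(np.real(np.linalg.eigvals(upper))))
    if c <= 0:
        return dist
    out = dist + c
    np.fill_diagonal(out, 0.0)
    return out


def build_functional_space(
    dist: np.ndarray,
    max_dim: int = 4,
    species_ids: list[str] | None = None,
    cailliez: bool = False,
) -> FunctionalSpace:
    """Classical PCoA of a trait distance matrix with quality scoring.

    Negative eigenvalues are dropped (optionally avoided with the Cailliez
    additive correction).  For each candidate dimensionality ``m`` from 2 to
    ``max_dim`` the quality score is the mean squared deviation between the
    input distances and the Euclidean distances in the first ``m`` axes,
    after rescaling the Euclidean distances so their maximum matches the
    input's.  The chosen dimensionality minimizes the score.
    """
    dist = np.asarray(dist, dtype=float)
    S = dist.shape[0]
    if species_ids is None:
        species_ids = [f"sp{i}" for i in range(S)]
    if max_dim >= S:
        raise ValueError("max_dim must be smaller than the number of species")
    if not np.any(dist > 0):
        raise ValueError("degenerate functional space: all distances are zero")
    if cailliez:
        dist_used = _cailliez_corrected(dist)
    else:
        dist_used = dist
    import warnings

    with warnings.catch_warnings():
        # non-Euclidean Gower matrices routinely produce negative
        # eigenvalues; they are dropped below, so the warning is noise here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(
            DistanceMatrix(dist_used, ids=species_ids), method="eigh",
            number_of_dimensions=0,
        )
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    keep = eig > max(eig.max(), 0) * 1e-9
    coords = coords[:, keep]
    eig = eig[keep]

    cond = np.triu_indices(S, k=1)
    d_in = dist[cond]
    quality: dict[int, float] = {}
    hi = min(max_dim, coords.shape[1])
    for m in range(2, hi + 1):
        d_euc = pdist(coords[:, :m])
        scale = d_in.max() / d_euc.max() if d_euc.max() > 0 else 1.0
        quality[m] = float(np.mean((d_in - scale * d_euc) ** 2))
    if not quality:
        raise ValueError("fewer than two positive PCoA axes")
    chosen = min(quality, key=lambda m: (quality[m], m))
    return FunctionalSpace(
        species_ids=list(species_ids),
        coordinates=coords,
        eigenvalues=eig,
        quality=quality,
        chosen_dim=chosen,
        input_distances=dist,
    )


def _hull_volume(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except (QhullError, ValueError):
        return np.nan


def functional_richness_timeseries(
    space: FunctionalSpace, presence: PresenceMatrix
) -> pd.DataFrame:
    """Per-bin convex-hull volume as a percentage of the global pool's hull.

    Bins with too few affinely independent points for a full-dimensional
    hull are flagged missing (NaN).
    """
    pos = {sid: i for i, sid in enumerate(space.species_ids)}
    missing = [s for s in presence.species_ids if s not in pos]
    if missing:
        raise KeyError(f"species missing from functional space: {missing[:5]}")
    idx = np.array([pos[s] for s in presence.species_ids], dtype=np.int64)
    coords = space.chosen_coordinates()[idx]
    global_vol = _hull_volume(coords)
    if not np.isfinite(global_vol) or global_vol <= 0:
        raise ValueError("global convex hull is degenerate")
    rows = []
    for b in range(presence.n_bins):
        mask = presence.presence[:, b]
        vol = _hull_volume(coords[mask]) if mask.any() else np.nan
        rows.append(
            {
                "bin_old": presence.bin_old[b],
                "bin_young": presence.bin_young[b],
                "n_species": int(mask.sum()),
                "hull_volume": vol,
                "functional_richness": 100.0 * vol / global_vol,
            }
        )
    return pd.DataFrame(rows)


def _metric_evaluator(metric: str, traits: SpeciesTraitTable, space):
    """Return f(pool_index_array) -> metric value for a species subset."""
    if metric in ("n_fe", "redundancy", "over_redundancy"):
        pos = {"n_fe": 0, "redundancy": 1, "over_redundancy": 2}[metric]

        def fe_eval(idx: np.ndarray) -> float:
            return float(_fe_metrics_for_subset(traits.states[idx])[pos])

        return fe_eval
    if metric == "functional_richness":
        if space is None:
            raise ValueError("functional_richness needs a FunctionalSpace")
        coords = space.chosen_coordinates()
        global_vol = _hull_volume(coords)

        def fr_eval(idx: np.ndarray) -> float:
            return 100.0 * _hull_volume(coords[idx]) / global_vol

        return fr_eval
    raise ValueError(f"unknown metric {metric!r}")


def null_expectation(
    metric: str,
    presence: PresenceMatrix,
    pool: SpeciesTraitTable,
    n_iter: int = 999,
    seed: int = 0,
    space: FunctionalSpace | None = None,
) -> pd.DataFrame:
    """Richness-matched null model for a named FD metric.

    For each bin, ``n_iter`` random subsets of the observed bin richness are
    drawn from the global pool without replacement and the metric is
    recomputed; the observed value is compared two-sided against the
    2.5-97.5% quantile envelope.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    idx_in_pool = _align_presence_to_traits(presence, pool)
    if metric == "functional_richness" and space is None:
        space = build_functional_space(
            gower_distance_matrix(pool),
            max_dim=min(4, pool.n_species - 1),
            species_ids=pool.species_ids,
        )
    evaluate = _metric_evaluator(metric, pool, space)
    S = pool.n_species
    rows = []
    for b in range(presence.n_bins):
        mask = presence.presence[:, b]
        k = int(mask.sum())
        if k > S:
            raise ValueError("bin richness exceeds pool size")
        if k == 0:
            rows.append(
                {
                    "bin_old": presence.bin_old[b],
                    "bin_young": presence.bin_young[b],
                    "n_species": 0,
                    "observed": np.nan,
                    "null_mean": np.nan,
                    "q025": np.nan,
                    "q975": np.nan,
                    "significant": False,
                }
            )
            continue
        observed = evaluate(idx_in_pool[mask])
        draws = np.empty(n_iter)
        for i in range(n_iter):
            draws[i] = evaluate(rng.choice(S, size=k, replace=False))
        finite = draws[np.isfinite(draws)]
        q025, q975 = np.quantile(finite, [0.025, 0.975])
        rows.append(
            {
                "bin_old": presence.bin_old[b],
                "bin_young": presence.bin_young[b],
                "n_species": k,
                "observed": observed,
                "null_mean": float(finite.mean()),
                "q025": float(q025),
                "q975": float(q975),
                "significant": bool(observed < q025 or observed > q975),
            }
        )
    return pd.DataFrame(rows)


def fd_timeseries(
    presence: PresenceMatrix,
    traits: SpeciesTraitTable,
    space: FunctionalSpace | None = None,
) -> pd.DataFrame:
    """Combined per-bin FD table: species, FEs, redundancy, over-redundancy
    and functional richness."""
    fe = fe_timeseries_metrics(presence, traits)
    if space is None:
        space = build_functional_space(
            gower_distance_matrix(traits),
            max_dim=min(4, traits.n_species - 1),
            species_ids=traits.species_ids,
        )
    fr = functional_richness_timeseries(space, presence)
    fe["functional_richness"] = fr["functional_richness"]
    return fe


def fd_with_uncertainty(
    longevity_sets,
    traits: SpeciesTraitTable,
    bin_width: float = 1.0,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """FD time series over replicate longevity sets (dating uncertainty).

    Every metric is recomputed per replicate; the median and the requested
    quantile band are reported per bin.
    """
    from .data_io import bin_presence

    space = build_functional_space(
        gower_distance_matrix(traits),
        max_dim=min(4, traits.n_species - 1),
        species_ids=traits.species_ids,
    )
    per_rep = []
    for lon in longevity_sets:
        presence = bin_presence(lon, bin_width=bin_width)
        per_rep.append(fd_timeseries(presence, traits, space=space))
    stacked = pd.concat(per_rep, keys=range(len(per_rep)), names=["replicate"])
    metrics = ["n_species", "n_fe", "redundancy", "over_redundancy", "functional_richness"]
    grouped = stacked.groupby(["bin_old", "bin_young"], sort=False)[metrics]
    out = grouped.median().add_suffix("_median")
    lo = grouped.quantile(quantiles[0]).add_suffix("_lo")
    hi = grouped.quantile(quantiles[1]).add_suffix("_hi")
    return pd.concat([out, lo, hi], axis=1).reset_index()
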