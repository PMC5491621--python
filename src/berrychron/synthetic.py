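"""Synthetic multi-omic stage x replicate datasets with known ground truth.

Emulates a developmental time-course design — by default 12 ordered
stages (Eichhorn-Lorenz labels EL 27 … EL 38 spanning fruit set to
ripeness) with 3 biological replicates each — in which metabolite and
protein features follow a small number of temporal archetype profiles
(early-high, veraison-peak, late-accumulating, monotone ramps, switches).
Measurements receive multiplicative lognormal noise and stage-independent
dropout (zeros, the dialect's "not detected" marker), and designated
feature pairs or archetype pairs carry planted lag-k causal dependencies
so every downstream stage of the pipeline has a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, SampleDesign
from .quantify import SpectralCountTable

EL_STAGES = (
    "EL27", "EL29", "EL30", "EL31", "EL32", "EL33",
    "EL34", "EL35", "EL36", "EL37", "EL37.5", "EL38",
)


@dataclass(frozen=True)
class CausalLink:
    """A planted lagged dependency: effect(t) += coefficient * cause(t - lag).

    ``level`` is ``"feature"`` (cause/effect are feature ids) or
    ``"archetype"`` (cause/effect are 0-based archetype indices, and the
    dependency is planted in the archetype profiles themselves so that
    every member feature inherits it).
    """

    cause: object
    effect: object
    lag: int
    coefficient: float
    level: str = "feature"

    def __post_init__(self):
        if self.lag not in (1, 2, 3):
            raise ValueError(f"lag must be 1, 2 or 3, got {self.lag}")
        if not math.isfinite(self.coefficient):
            raise ValueError("coefficient must be finite")
        if self.level not in ("feature", "archetype"):
            raise ValueError(f"level must be 'feature' or 'archetype', got {self.level!r}")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    Defaults mirror the study design the generator emulates: 12 ordered
    stages, 3 biological replicates, 12 temporal archetypes. ``noise_cv``
    is the coefficient of variation of the multiplicative lognormal
    measurement noise; ``dropout_rate`` the probability that a single
    measurement is zeroed (applied after noise, independently per cell).
    """

    n_stages: int = 12
    n_replicates: int = 3
    n_metabolites: int = 48
    n_proteins: int = 96
    n_archetypes: int = 12
    noise_cv: float = 0.15
    dropout_rate: float = 0.0
    causal_links: list[CausalLink] = field(default_factory=list)
    mean_spectral_count: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        max_lag = max((l.lag for l in self.causal_links), default=1)
        if self.n_stages < max_lag + 5:
            raise ValueError(
                f"n_stages={self.n_stages} too short: need >= max lag + 5 = {max_lag + 5} "
                "for residual degrees of freedom in the Granger F-test"
            )
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_replicates < 1 or self.n_archetypes < 1:
            raise ValueError("n_replicates and n_archetypes must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: feature memberships, causal edges, archetype profiles."""

    archetype_of_feature: dict[str, int]
    true_edges: list[CausalLink]
    true_profiles: pd.DataFrame  # archetype x stage, after planted archetype links

    def edge_records(self):
        for e in self.true_edges:
            yield (e.cause, e.effect, e.lag, e.coefficient, e.level)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _shape_library(n_stages: int) -> list[np.ndarray]:
    """Fixed library of smooth temporal shapes over [0, 1].

    Order matters: the first two are exactly mirrored linear ramps.
    Shapes emulate the cluster patterns seen in developmental omics:
    monotone ramps, ripening-onset switches, stage-specific peaks,
    a mid-development valley and late-accumulating curves.
    """
    t = np.linspace(0.0, 1.0, n_stages)
    return [
        t,                                   # monotone up
        -t,                                  # monotone down
        _logistic((t - 0.5) / 0.04),         # switch up at veraison (mid)
        -_logistic((t - 0.5) / 0.04),        # switch down at veraison
        _gauss(t, 0.15, 0.10),               # early peak
        _gauss(t, 0.40, 0.10),               # pre-veraison peak
        _gauss(t, 0.65, 0.10),               # post-veraison peak
        _gauss(t, 0.90, 0.10),               # ripening peak
        -_gauss(t, 0.50, 0.18),              # mid valley
        t ** 4,                              # late accumulating (convex)
        _logistic((t - 0.25) / 0.06),        # early switch up
        -_logistic((t - 0.75) / 0.06),       # late switch down
        (1.0 - t) ** 4,                      # early high, fast decay
        _gauss(t, 0.30, 0.07),               # narrow lag-phase peak
        _gauss(t, 0.78, 0.07),               # narrow post-veraison peak
        t * (1.0 - t) * _logistic((t - 0.5) / 0.2),  # skewed late hump
    ]


def generate_archetypes(spec: SyntheticSpec) -> pd.DataFrame:
    """Archetype x stage profile matrix, each row mean 0 / unit variance.

    Profiles are drawn in order from a fixed parametric library; they are
    rejected as indistinguishable if the stage grid is too coarse to
    separate them (pairwise correlation above 0.999).
    """
    library = _shape_library(spec.n_stages)
    if spec.n_archetypes > len(library):
        raise ValueError(
            f"n_archetypes={spec.n_archetypes} exceeds the {len(library)} distinct "
            "shapes reachable in the library"
        )
    rows = []
    for shape in library[: spec.n_archetypes]:
        sd = shape.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate constant shape at this n_stages")
        rows.append((shape - shape.mean()) / sd)
    profiles = np.array(rows)
    if spec.n_archetypes > 1:
        corr = np.corrcoef(profiles)
        iu = np.triu_indices(spec.n_archetypes, k=1)
        if np.any(corr[iu] > 0.999):
            raise ValueError(
                f"archetype shapes indistinguishable at n_stages={spec.n_stages}"
            )
    stages = _stage_labels(spec.n_stages)
    return pd.DataFrame(profiles, index=range(spec.n_archetypes), columns=stages)


def _stage_labels(n_stages: int) -> list[str]:
    if n_stages == len(EL_STAGES):
        return list(EL_STAGES)
    return [f"T{i + 1:02d}" for i in range(n_stages)]


def _dependency_order(feature_ids, links_by_effect) -> list[str]:
    """Topological order so every cause is realized before its effects."""
    order, state = [], {}

    def visit(fid):
        if state.get(fid) == 2:
            return
        if state.get(fid) == 1:
            raise ValueError(f"cyclic feature-level causal links involving {fid!r}")
        state[fid] = 1
        for link in links_by_effect.get(fid, ()):
            visit(link.cause)
        state[fid] = 2
        order.append(fid)

    for fid in feature_ids:
        visit(fid)
    return order


def _lag_shift(series: np.ndarray, lag: int) -> np.ndarray:
    """Shift a stage series right by ``lag``, padding with its first value."""
    return np.concatenate([np.repeat(series[:1], lag, axis=0), series[:-lag]])


def _mix_driven(own: np.ndarray, cause_lagged: np.ndarray, coeff: float) -> np.ndarray:
    """Convex causal mixing: a coefficient of c makes the effect c-parts
    lagged cause and (1 - c)-parts its own archetype dynamics."""
    w = max(0.0, 1.0 - abs(coeff))
    return w * own + coeff * cause_lagged


def _feature_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Per-feature RNG streams spawned from one global seed.

    Spawning keeps streams stable under growth: adding features never
    perturbs the values of existing ones.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def generate_design(spec: SyntheticSpec) -> SampleDesign:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0].entropy % 2**31)
    stages = _stage_labels(spec.n_stages)
    rows = []
    for stage in stages:
        for rep in range(1, spec.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{stage}_r{rep}",
                    "stage": stage,
                    "replicate": str(rep),
                    "fresh_weight": float(rng.uniform(80.0, 120.0)),
                    "internal_standard_intensity": float(rng.uniform(0.8, 1.2)),
                    "total_ion_intensity": float(rng.uniform(0.8, 1.2) * 1e6),
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleDesign(table, stage_order=stages)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[SpectralCountTable, AbundanceMatrix, SampleDesign, GroundTruth]:
    """Generate (protein spectral counts, raw metabolite areas, design, truth).

    Per feature: the stage profile is its archetype's profile, shifted to
    a positive baseline, with planted feature-level lag dependencies
    added; each replicate measurement is that profile value times a
    lognormal factor of the requested CV, then zeroed with probability
    ``dropout_rate``. Raw metabolite values are multiplied by the
    sample's fresh weight and reference intensity so that metabolite
    normalization exactly inverts them; protein profiles are scaled to a
    target mean spectral count and rounded half-up to integers.
    """
    for link in spec.causal_links:
        if link.lag >= spec.n_stages:
            raise ValueError(f"lag {link.lag} >= n_stages {spec.n_stages}")

    archetypes = generate_archetypes(spec)
    profiles = archetypes.to_numpy().copy()
    arch_links: dict[int, list[CausalLink]] = {}
    for link in spec.causal_links:
        if link.level == "archetype":
            arch_links.setdefault(link.effect, []).append(link)
    # chains (a -> b -> c) propagate through realized profiles, so each
    # planted edge is a clean one-step lag dependency on its direct cause
    for aid in _dependency_order(list(range(spec.n_archetypes)), arch_links):
        for link in arch_links.get(aid, ()):
            profiles[aid] = _mix_driven(
                profiles[aid], _lag_shift(profiles[link.cause], link.lag), link.coefficient
            )
    stages = list(archetypes.columns)

    met_ids = [f"met_{i + 1:03d}" for i in range(spec.n_metabolites)]
    prot_ids = [f"prot_{i + 1:03d}" for i in range(spec.n_proteins)]
    feature_ids = met_ids + prot_ids
    n_features = len(feature_ids)
    membership = {fid: i % spec.n_archetypes for i, fid in enumerate(feature_ids)}

    # positive per-feature mean profiles (shifted archetype shapes)
    shapes = {}
    for fid in feature_ids:
        prof = profiles[membership[fid]]
        shapes[fid] = prof - prof.min() + 0.5

    feature_links: dict[str, list[CausalLink]] = {}
    for link in spec.causal_links:
        if link.level == "feature":
            if link.cause not in shapes or link.effect not in shapes:
                raise ValueError(f"unknown feature id in causal link: {link}")
            feature_links.setdefault(link.effect, []).append(link)
    order = _dependency_order(feature_ids, feature_links)

    design = generate_design(spec)
    streams = {fid: s for fid, s in zip(feature_ids, _feature_streams(spec.seed, n_features + 1))}
    aux_stream = _feature_streams(spec.seed, n_features + 1)[-1]
    n_cells = (spec.n_stages, spec.n_replicates)

    # Effects receive the cause's *realized* (noisy) lagged values, replicate
    # by replicate, so the planted dependency is detectable in the measured
    # series and not just in the noiseless shapes.
    cells: dict[str, np.ndarray] = {}
    for fid in order:
        rng = streams[fid]
        noise = _lognormal_factors(rng, spec.noise_cv, n_cells)
        cell = shapes[fid][:, None] * noise
        for link in feature_links.get(fid, ()):
            own_w = max(0.0, 1.0 - abs(link.coefficient))
            cell = own_w * cell + link.coefficient * np.vstack(
                [np.repeat(cells[link.cause][:1], link.lag, axis=0),
                 cells[link.cause][: -link.lag]]
            )
        if spec.dropout_rate > 0:
            cell = cell * (rng.random(n_cells) >= spec.dropout_rate)
        cells[fid] = cell
    values = np.array([cells[fid].ravel() for fid in feature_ids])
    values_df = pd.DataFrame(values, index=feature_ids, columns=design.samples)

    # metabolites: half GC-MS, half LC-MS; raw = abundance * fw * reference
    n_gc = (spec.n_metabolites + 1) // 2
    kinds = pd.Series(
        ["metabolite_gc"] * n_gc
        + ["metabolite_lc"] * (spec.n_metabolites - n_gc)
        + ["protein"] * spec.n_proteins,
        index=feature_ids,
    )
    fw = design.table["fresh_weight"]
    is_ref = design.table["internal_standard_intensity"]
    ti_ref = design.table["total_ion_intensity"]
    met_raw = values_df.loc[met_ids] * 1e3  # peak-area scale
    gc_mask = kinds.loc[met_ids] == "metabolite_gc"
    met_raw.loc[gc_mask] = met_raw.loc[gc_mask].mul(fw * is_ref, axis=1)
    met_raw.loc[~gc_mask] = met_raw.loc[~gc_mask].mul(fw * ti_ref, axis=1)
    metabolites = AbundanceMatrix(met_raw, kinds.loc[met_ids])

    prot_values = values_df.loc[prot_ids]
    overall_mean = float(prot_values.to_numpy().mean()) if prot_values.size else 1.0
    scale = spec.mean_spectral_count / overall_mean if overall_mean > 0 else 0.0
    counts = np.floor(prot_values.to_numpy() * scale + 0.5).astype(int)  # round half-up
    lengths = pd.Series(
        aux_stream.integers(150, 1200, size=spec.n_proteins), index=prot_ids
    )
    spectral = SpectralCountTable(
        pd.DataFrame(counts, index=prot_ids, columns=design.samples), lengths
    )

    truth = GroundTruth(
        archetype_of_feature=membership,
        true_edges=list(spec.causal_links),
        true_profiles=pd.DataFrame(profiles, index=range(spec.n_archetypes), columns=stages),
    )
    return spectral, metabolites, design, truth


def generate_null_pair(length: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two independent standard-normal series, for null calibration."""
    if length < 6:
        raise ValueError("length must be >= 6")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(length), rng.standard_normal(length)
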