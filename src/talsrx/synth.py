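"""Synthetic KASP plate simulator.

Real KASP scatter plots are graded on a 0-100 rubric describing the geometry
of the three genotype clouds (two homozygote clusters at the extremes of the
HEX and FAM axes, heterozygotes on the line between them) and the behaviour of
the no-template controls.  This module realizes each score class of that
rubric generatively: clusters are isotropic Gaussians around class-specific
centroids, degraded by per-class shifts, heterozygote displacements,
exponential "tails" toward the origin and diffusion multipliers, with NTC
wells either at background level or — for the NTC-contamination class (score
10) — displaced into the signal range.

Signal scale follows the relative-fluorescence magnitudes seen on real
plates: background level 0.33, saturated level 1.30 (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .plate import DNA, NTC, Dataset, PlateRecord, Well, validate_score

#: Background (no amplification) relative signal level on each channel.
BACKGROUND_LEVEL = 0.33
#: Saturated (full amplification) relative signal level.
HIGH_LEVEL = 1.30

NTC_BACKGROUND = "background"
NTC_SPECIFIC = "specific"


@dataclass(frozen=True)
class MorphologySpec:
    """Generative parameters for one score class of the typing rubric.

    ``hom_A`` is the cluster homozygous for the HEX-reported allele (high x,
    low y); ``hom_B`` for the FAM-reported allele (low x, high y).
    """

    score: int
    n_AA: int = 40
    n_BB: int = 40
    n_AB: int = 14
    hom_A_centroid: tuple[float, float] = (HIGH_LEVEL, BACKGROUND_LEVEL)
    hom_B_centroid: tuple[float, float] = (BACKGROUND_LEVEL, HIGH_LEVEL)
    het_centroid: tuple[float, float] | None = None  # None -> homozygote midpoint
    cluster_sd: float = 0.03
    het_offset_perp: float = 0.0
    het_shift_along: float = 0.0
    hom_shift: float = 0.0
    hom_shift_which: str = "both"  # "A", "B" or "both"
    tail_scale: float = 0.0
    tail_fraction: float = 0.35
    diffusion_factor: float = 1.0
    ntc_mode: str = NTC_BACKGROUND
    ntc_sd: float = 0.015

    def __post_init__(self) -> None:
        validate_score(self.score)
        if self.n_AA + self.n_BB + self.n_AB != 94:
            raise ValueError(
                f"genotype well counts must sum to 94, got "
                f"{self.n_AA}+{self.n_BB}+{self.n_AB}"
            )
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be non-negative")
        if self.diffusion_factor < 1:
            raise ValueError("diffusion_factor must be >= 1")
        if self.ntc_mode not in (NTC_BACKGROUND, NTC_SPECIFIC):
            raise ValueError(f"unknown ntc_mode {self.ntc_mode!r}")
        if self.hom_shift_which not in ("A", "B", "both"):
            raise ValueError(f"hom_shift_which must be A, B or both")

    # -- realized cluster centroids -------------------------------------

    def hom_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Homozygote centroids after any axis-parallel shift toward background."""
        a = np.asarray(self.hom_A_centroid, dtype=float)
        b = np.asarray(self.hom_B_centroid, dtype=float)
        if self.hom_shift:
            # a shifted homozygote slides along its dominant axis toward background
            if self.hom_shift_which in ("A", "both"):
                a = a - np.array([self.hom_shift, 0.0])
            if self.hom_shift_which in ("B", "both"):
                b = b - np.array([0.0, self.hom_shift])
        return a, b

    def het_center(self) -> np.ndarray:
        """Heterozygote centroid after along-line shift and perpendicular offset."""
        a, b = self.hom_centroids()
        base = (
            np.asarray(self.het_centroid, dtype=float)
            if self.het_centroid is not None
            else 0.5 * (a + b)
        )
        line = b - a
        norm = np.linalg.norm(line)
        if norm == 0:
            return base
        u = line / norm
        perp = np.array([-u[1], u[0]])
        return base + self.het_shift_along * u + self.het_offset_perp * perp


def default_spec(score: int) -> MorphologySpec:
    """Canonical morphology for a rubric score class.

    100  clean plate: tight independent clusters, het at the midpoint.
    90   het cloud deviates perpendicular to the homozygote line.
    80   het cloud shifted along the homozygote line.
    70   one homozygote shifted along its axis (or trailing, via
         ``score70_trailing``-style override by the caller).
    60   both homozygotes shifted along their axes.
    50   homozygotes trail toward the origin.
    40   moderate diffusion and slight shifts; still typeable.
    30   strong diffusion plus het shift; barely separable.
    20   heavy diffusion, clusters overlap.
    10   NTC wells show marked specificity (amplification without template).
    0    diffusion so large all clusters merge.
    """
    validate_score(score)
    base = MorphologySpec(score=score)
    per_class: dict[int, dict] = {
        100: {},
        90: {"het_offset_perp": 0.28},
        80: {"het_shift_along": 0.28},
        70: {"hom_shift": 0.30, "hom_shift_which": "A"},
        60: {"hom_shift": 0.30, "hom_shift_which": "both"},
        50: {"tail_scale": 0.28},
        40: {"diffusion_factor": 2.5, "hom_shift": 0.10, "hom_shift_which": "both"},
        30: {"diffusion_factor": 4.0, "het_shift_along": 0.20},
        20: {"diffusion_factor": 6.0},
        10: {"ntc_mode": NTC_SPECIFIC, "cluster_sd": 0.05},
        0: {"diffusion_factor": 10.0},
    }
    return replace(base, **per_class[score])


def score70_trailing_spec() -> MorphologySpec:
    """Alternative score-70 realization: one homozygote trailing, not shifted."""
    return replace(
        default_spec(70), hom_shift=0.0, tail_scale=0.28, tail_fraction=0.35,
        hom_shift_which="A",
    )


def sample_plate(
    spec: MorphologySpec, rng: np.random.Generator, snp_id: str = "synthetic"
) -> PlateRecord:
    """Draw one plate from a morphology spec.

    DNA wells: per-genotype isotropic Gaussians around the realized centroids
    with sd ``cluster_sd * diffusion_factor``; for homozygotes a
    ``tail_fraction`` of points receive an additional Exponential(tail_scale)
    displacement toward the origin.  NTC wells sit at background unless
    ``ntc_mode == "specific"``.  Coordinates are clipped at zero (fluorescence
    is non-negative).  The generating genotype is recorded in each well and
    ``label = spec.score``.
    """
    a, b = spec.hom_centroids()
    het = spec.het_center()
    sd = spec.cluster_sd * spec.diffusion_factor

    wells: list[Well] = []
    tail_targets = {"AA": a, "BB": b}
    for genotype, center, count in (
        ("AA", a, spec.n_AA),
        ("BB", b, spec.n_BB),
        ("AB", het, spec.n_AB),
    ):
        pts = center + rng.normal(0.0, sd, size=(count, 2))
        if spec.tail_scale > 0 and genotype in tail_targets:
            origin_dir = -center / max(np.linalg.norm(center), 1e-12)
            is_tailed = rng.random(count) < spec.tail_fraction
            lengths = rng.exponential(spec.tail_scale, size=count)
            pts = pts + np.where(is_tailed[:, None], lengths[:, None] * origin_dir, 0.0)
        pts = np.clip(pts, 0.0, None)
        wells.extend(
            Well(x=float(p[0]), y=float(p[1]), role=DNA, genotype=genotype)
            for p in pts
        )

    if spec.ntc_mode == NTC_SPECIFIC:
        # nonspecific amplification: NTC wells land in the signal range
        ntc_center = 0.5 * (a + b)
    else:
        ntc_center = np.array([BACKGROUND_LEVEL, BACKGROUND_LEVEL])
    ntc_pts = np.clip(ntc_center + rng.normal(0.0, spec.ntc_sd, size=(2, 2)), 0.0, None)
    wells.extend(
        Well(x=float(p[0]), y=float(p[1]), role=NTC) for p in ntc_pts
    )
    return PlateRecord(snp_id=snp_id, wells=tuple(wells), label=spec.score)


_JITTERED_FIELDS = (
    "cluster_sd",
    "het_offset_perp",
    "het_shift_along",
    "hom_shift",
    "tail_scale",
    "ntc_sd",
)


def jitter_spec(
    spec: MorphologySpec, rng: np.random.Generator, rel: float = 0.2
) -> MorphologySpec:
    """Perturb each continuous morphology parameter within ±``rel`` of its value.

    Gives a generated class internal variation while keeping its identity;
    diffusion_factor is jittered on its excess over 1 so it never drops below
    the no-diffusion floor.
    """
    changes = {}
    for name in _JITTERED_FIELDS:
        v = getattr(spec, name)
        if v:
            changes[name] = v * (1.0 + rel * rng.uniform(-1, 1))
    excess = spec.diffusion_factor - 1.0
    if excess > 0:
        changes["diffusion_factor"] = 1.0 + excess * (1.0 + rel * rng.uniform(-1, 1))
    return replace(spec, **changes)


def generate_dataset(
    class_counts: dict[int, int],
    rng: np.random.Generator | int,
    jitter: float = 0.2,
    spec_overrides: dict[int, MorphologySpec] | None = None,
) -> Dataset:
    """Generate a labeled dataset with ``class_counts[score]`` plates per class.

    Per-plate specs are jittered around the class default so classes have
    internal variation.  Deterministic for a fixed seed: all randomness flows
    from one root generator.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    records = []
    for score in sorted(class_counts, reverse=True):
        count = class_counts[score]
        if count < 0:
            raise ValueError(f"negative count for score {score}")
        base = (
            spec_overrides[score]
            if spec_overrides and score in spec_overrides
            else default_spec(score)
        )
        for i in range(count):
            spec = jitter_spec(base, rng, rel=jitter) if jitter > 0 else base
            records.append(
                sample_plate(spec, rng, snp_id=f"SYN{score:03d}_{i:04d}")
            )
    return Dataset(records=records)
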