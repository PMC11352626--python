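"""Synthetic cohort and expression-matrix generation.

The cohort generator is the exact inverse of the decay-to-plateau survival
model: each subject is "cured" with probability equal to the group's
plateau and never experiences the event; non-cured subjects draw an
exponential event time with rate ln(2)/half-life.  Censoring emulates
uniform accrual with an administrative cut-off, i.e. a Uniform(min, max)
censor time per subject.  Progression and death are coupled so that a PFS
event is progression or death, whichever comes first -- death always
implies a PFS event and ``pfs_time <= os_time`` holds for every record.

Raw IHC readings are sampled to be consistent with each subject's binary
marker call (a SATB1-positive subject always receives an (SI, PP) pair
with product > 1, and so on), so scoring the measurements reproduces the
marker flags exactly.  Clinical covariates are sampled independently of
the markers.

The expression generator plants gene-set signatures: member genes of a
planted set share a latent factor, and the designated driver transcript is
correlated with that factor so that the set's enrichment score tracks the
driver at approximately the requested correlation.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .ihc import IHCMeasurement, Intensity, Marker, intensity_from_score
from .survival import SurvivalRecord

__all__ = [
    "CELLS",
    "GroupSpec",
    "CensoringSpec",
    "CohortSpec",
    "SyntheticCohort",
    "PlantedSignal",
    "load_spec",
    "paper_like_spec",
    "simulate_cohort",
    "simulate_expression",
]

LN2 = math.log(2.0)

#: The four joint marker cells: SATB1 +/- crossed with p16 +/-.
CELLS = ("S+P-", "S+P+", "S-P+", "S-P-")


@dataclass(frozen=True)
class GroupSpec:
    """One survival group: the marker cells it covers and its cure-model truth."""

    name: str
    cells: tuple
    os_plateau: float
    os_half_life_months: float
    pfs_plateau: float
    pfs_half_life_months: float


@dataclass(frozen=True)
class CensoringSpec:
    admin_max_months: float = 197.0
    min_months: float = 1.0
    uniform_entry: bool = True


@dataclass
class CohortSpec:
    """Generating truth for a synthetic cohort."""

    n: int
    groups: List[GroupSpec]
    marker_joint: Dict[str, float]
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    covariate_distributions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    age_quantiles: Optional[Dict[str, List[float]]] = None
    seed: int = 0
    # True: allocate marker cells deterministically in proportion to
    # marker_joint (largest-remainder rounding, order shuffled) -- emulates a
    # cohort whose marker table is fixed.  False: i.i.d. multinomial draw.
    exact_cells: bool = False

    def validate(self) -> None:
        problems = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        joint_sum = sum(self.marker_joint.get(c, 0.0) for c in CELLS)
        if abs(joint_sum - 1.0) > 1e-6:
            problems.append(f"marker_joint fractions must sum to 1, got {joint_sum}")
        unknown = set(self.marker_joint) - set(CELLS)
        if unknown:
            problems.append(f"unknown marker cells: {sorted(unknown)}")
        covered: List[str] = []
        for g in self.groups:
            covered.extend(g.cells)
            for name, p in (("os_plateau", g.os_plateau), ("pfs_plateau", g.pfs_plateau)):
                if not (0.0 <= p <= 1.0):
                    problems.append(f"group {g.name!r}: {name} must lie in [0, 1], got {p}")
            for name, hl in (
                ("os_half_life_months", g.os_half_life_months),
                ("pfs_half_life_months", g.pfs_half_life_months),
            ):
                if not hl > 0:
                    problems.append(f"group {g.name!r}: {name} must be > 0, got {hl}")
        if sorted(covered) != sorted(c for c in CELLS if self.marker_joint.get(c, 0.0) > 0):
            problems.append(
                "group cells must partition the marker cells with positive mass; "
                f"covered={sorted(covered)}"
            )
        if not (0 < self.censoring.min_months <= self.censoring.admin_max_months):
            problems.append("censoring window must satisfy 0 < min_months <= admin_max_months")
        for var, dist in self.covariate_distributions.items():
            if not dist or any(w < 0 for w in dist.values()) or sum(dist.values()) <= 0:
                problems.append(f"covariate {var!r}: weights must be non-negative with positive sum")
        if problems:
            raise ValidationError("invalid cohort spec:\n  - " + "\n  - ".join(problems))


@dataclass
class SyntheticCohort:
    records: List[SurvivalRecord]
    measurements: List[IHCMeasurement]
    truth: CohortSpec

    def content_hash(self) -> str:
        """Hash of the generated records, for determinism checks."""
        h = hashlib.sha256()
        for r in self.records:
            h.update(
                f"{r.sample_id}|{r.time:.10f}|{r.os_event}|{r.pfs_time:.10f}|"
                f"{r.pfs_event}|{r.satb1_positive}|{r.p16_positive}".encode()
            )
        return h.hexdigest()


def load_spec(source: Union[str, Dict]) -> CohortSpec:
    """Build a CohortSpec from a YAML path or an already-parsed mapping."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    cens = raw.get("censoring", {})
    groups = [
        GroupSpec(
            name=g["name"],
            cells=tuple(g["cells"]),
            os_plateau=float(g["os_plateau"]),
            os_half_life_months=float(g["os_half_life_months"]),
            pfs_plateau=float(g["pfs_plateau"]),
            pfs_half_life_months=float(g["pfs_half_life_months"]),
        )
        for g in raw["groups"]
    ]
    spec = CohortSpec(
        n=int(raw["n"]),
        groups=groups,
        marker_joint={str(k): float(v) for k, v in raw["marker_joint"].items()},
        censoring=CensoringSpec(
            admin_max_months=float(cens.get("admin_max_months", 197.0)),
            min_months=float(cens.get("min_months", 1.0)),
            uniform_entry=bool(cens.get("uniform_entry", True)),
        ),
        covariate_distributions={
            str(var): {str(k): float(v) for k, v in dist.items()}
            for var, dist in raw.get("covariates", {}).items()
        },
        age_quantiles=raw.get("age_quantiles"),
        seed=int(raw.get("seed", 0)),
        exact_cells=bool(raw.get("exact_cells", False)),
    )
    spec.validate()
    return spec


def paper_like_spec() -> CohortSpec:
    """The packaged default: an 86-patient cohort with marker split 12/8/4/62
    and the fitted plateau/half-life values as generating truth."""
    from importlib.resources import files

    with files("hlstrat.data").joinpath("paper_like.yaml").open("r", encoding="utf-8") as fh:
        return load_spec(yaml.safe_load(fh))


def _cell_flags(cell: str) -> Dict[str, bool]:
    return {"satb1": cell.startswith("S+"), "p16": cell.endswith("P+")}


def _sample_satb1_measurement(rng: np.random.Generator, sample_id: str, positive: bool) -> IHCMeasurement:
    pp_ranges = {1: (0.0, 9.9), 2: (10.0, 50.0), 3: (50.1, 100.0)}
    if positive:
        si = int(rng.choice([1, 2, 3], p=[0.2, 0.4, 0.4]))
        pp_score = int(rng.choice([2, 3])) if si == 1 else int(rng.choice([1, 2, 3]))
    else:
        if rng.random() < 0.5:
            si, pp_score = 0, int(rng.choice([1, 2, 3]))
        else:
            si, pp_score = 1, 1
    lo, hi = pp_ranges[pp_score]
    percent = float(rng.uniform(lo, hi))
    return IHCMeasurement(sample_id, Marker.SATB1, intensity_from_score(si), percent)


def _sample_p16_measurement(rng: np.random.Generator, sample_id: str, positive: bool) -> IHCMeasurement:
    if positive:
        percent = float(rng.uniform(10.0, 100.0))
        intensity = Intensity(rng.choice(["weak", "moderate", "strong"]))
    else:
        percent = float(rng.uniform(0.0, 9.9))
        intensity = Intensity(rng.choice(["negative", "weak"]))
    return IHCMeasurement(sample_id, Marker.P16, intensity, percent)


def _sample_age(rng: np.random.Generator, age_quantiles: Optional[Dict[str, List[float]]]) -> float:
    if age_quantiles:
        q = np.asarray(age_quantiles["q"], dtype=float)
        ages = np.asarray(age_quantiles["age"], dtype=float)
    else:
        q = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        ages = np.array([18.0, 28.0, 41.0, 55.0, 86.0])
    return float(round(np.interp(rng.random(), q, ages), 1))


def simulate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> SyntheticCohort:
    """Draw a cohort from the cure-fraction model the spec describes.

    Fully reproducible: the same spec and seed give an identical cohort.
    ``seed`` overrides ``spec.seed`` when given.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cens = spec.censoring

    cell_names = [c for c in CELLS if spec.marker_joint.get(c, 0.0) > 0]
    probs = np.array([spec.marker_joint[c] for c in cell_names])
    probs = probs / probs.sum()
    cell_to_group = {}
    for g in spec.groups:
        for c in g.cells:
            cell_to_group[c] = g

    if spec.exact_cells:
        # largest-remainder allocation of n subjects to cells, order shuffled
        raw_counts = probs * spec.n
        counts = np.floor(raw_counts).astype(int)
        remainder = spec.n - counts.sum()
        order = np.argsort(-(raw_counts - counts))
        counts[order[:remainder]] += 1
        cell_idx = rng.permutation(np.repeat(np.arange(len(cell_names)), counts))
    else:
        cell_idx = rng.choice(len(cell_names), size=spec.n, p=probs)

    records: List[SurvivalRecord] = []
    measurements: List[IHCMeasurement] = []
    width = len(str(spec.n))
    for i in range(spec.n):
        sid = f"HL{i + 1:0{width}d}"
        cell = cell_names[cell_idx[i]]
        flags = _cell_flags(cell)
        g = cell_to_group[cell]

        # latent death time under the OS cure model
        cured_os = rng.random() < g.os_plateau
        t_death = math.inf if cured_os else float(rng.exponential(g.os_half_life_months / LN2))
        # latent progression time under the PFS cure model; PFS event is
        # progression or death, whichever first
        cured_pfs = rng.random() < g.pfs_plateau
        t_prog = math.inf if cured_pfs else float(rng.exponential(g.pfs_half_life_months / LN2))
        t_pfs = min(t_prog, t_death)

        if cens.uniform_entry:
            c_time = float(rng.uniform(cens.min_months, cens.admin_max_months))
        else:
            c_time = cens.admin_max_months

        os_time = min(t_death, c_time)
        os_event = t_death <= c_time
        pfs_time = min(t_pfs, c_time)
        pfs_event = t_pfs <= c_time

        covariates: Dict[str, object] = {}
        age = _sample_age(rng, spec.age_quantiles)
        covariates["age"] = age
        covariates["age_band"] = "<45" if age < 45 else ">=45"
        for var, dist in spec.covariate_distributions.items():
            cats = sorted(dist)
            weights = np.array([dist[c] for c in cats], dtype=float)
            covariates[var] = str(rng.choice(cats, p=weights / weights.sum()))

        records.append(
            SurvivalRecord(
                sample_id=sid,
                time=os_time,
                os_event=bool(os_event),
                pfs_time=pfs_time,
                pfs_event=bool(pfs_event),
                satb1_positive=flags["satb1"],
                p16_positive=flags["p16"],
                covariates=covariates,
            )
        )
        measurements.append(_sample_satb1_measurement(rng, sid, flags["satb1"]))
        measurements.append(_sample_p16_measurement(rng, sid, flags["p16"]))

    return SyntheticCohort(records=records, measurements=measurements, truth=spec)


# ---------------------------------------------------------------------------
# Expression matrices with planted gene-set signatures


@dataclass(frozen=True)
class PlantedSignal:
    """A gene set whose members share a latent factor tracked by a driver gene."""

    gene_set: tuple
    driver_gene: str
    target_r: float

    def __post_init__(self) -> None:
        if not self.gene_set:
            raise ValidationError("planted gene_set must be non-empty")
        if not abs(self.target_r) < 1:
            raise ValidationError(f"|target_r| must be < 1, got {self.target_r}")
        if self.driver_gene in self.gene_set:
            raise ValidationError(
                f"driver gene {self.driver_gene!r} must not be a member of its own set"
            )


# member genes load on the latent factor at 0.9; the driver's loading is
# inflated by ~5% to pre-compensate the rank-statistic attenuation of the
# enrichment score
_MEMBER_LOADING = 0.9
_DRIVER_COMPENSATION = 0.95


def simulate_expression(
    n_genes: int,
    samples: Union[int, Sequence[str]],
    planted: Sequence[Union[PlantedSignal, Dict]],
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x sample expression matrix with planted correlated signatures.

    Background genes are independent standard normals across samples.
    Planted sets whose members overlap, or that share a driver gene, are
    rejected.  Byte-identical output for a fixed seed.
    """
    if isinstance(samples, int):
        sample_names = [f"HLS{i + 1:02d}" for i in range(samples)]
    else:
        sample_names = list(samples)
    n_samples = len(sample_names)
    if n_samples < 2:
        raise ValidationError("need at least 2 samples")

    signals = [
        p if isinstance(p, PlantedSignal) else PlantedSignal(
            gene_set=tuple(p["gene_set"]), driver_gene=str(p["driver_gene"]),
            target_r=float(p["target_r"]),
        )
        for p in planted
    ]
    drivers = [s.driver_gene for s in signals]
    if len(set(drivers)) != len(drivers):
        raise ValidationError("planted signals must not share a driver gene")
    seen: set = set()
    for s in signals:
        members = set(s.gene_set)
        if seen & members:
            raise ValidationError(
                f"planted gene sets overlap on {sorted(seen & members)[:5]}"
            )
        seen |= members

    named = list(dict.fromkeys([g for s in signals for g in s.gene_set] + drivers))
    if n_genes < len(named):
        raise ValidationError(
            f"n_genes={n_genes} smaller than the {len(named)} named genes"
        )

    rng = np.random.default_rng(seed)
    rows: Dict[str, np.ndarray] = {}
    for s in signals:
        factor = rng.standard_normal(n_samples)
        a = _MEMBER_LOADING
        for gene in s.gene_set:
            rows[gene] = a * factor + math.sqrt(1 - a * a) * rng.standard_normal(n_samples)
        c = float(np.clip(s.target_r / _DRIVER_COMPENSATION, -0.999, 0.999))
        rows[s.driver_gene] = c * factor + math.sqrt(1 - c * c) * rng.standard_normal(n_samples)

    background = n_genes - len(named)
    for i in range(background):
        rows[f"BG{i + 1:05d}"] = rng.standard_normal(n_samples)

    return pd.DataFrame(rows, index=sample_names).T
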