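"""Synthetic treatment-plan generator with labeled anomaly injection.

Emulates the statistical structure of an institutional 4-field breast
protocol: two IMRT fields at ~290 MU, two tangent fields at ~200 MU,
SSD near 100 cm, correlated collimator jaw positions, gantry angles on an
equally-spaced beam pattern, and IMRT segment counts inside a protocol
range.  Anomalies are subtle protocol violations that keep the record
schema-valid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .schema import (
    FeatureSchema,
    PlanRecord,
    PlanTable,
    ABNORMAL_LABEL,
    NORMAL_LABEL,
    default_schema,
    validate_record,
)

__all__ = [
    "ProtocolConfig",
    "AnomalySpec",
    "GenConfig",
    "ANOMALY_TYPES",
    "generate_normal_plan",
    "inject_anomaly",
    "generate_dataset",
    "write_dataset",
    "protocol_violations",
]

ANOMALY_TYPES = (
    "mu_offset",
    "unequal_beam_spacing",
    "jaw_asymmetry",
    "segment_count_violation",
    "ssd_outlier",
    "mixed",
)

#: field slots, in column order: two IMRT fields then two tangents
IMRT_FIELDS = (0, 1)
TANGENT_FIELDS = (2, 3)

#: the equally-spaced four-beam gantry pattern normal plans draw from
EQUAL_SPACING_PATTERN = ("0", "90", "180", "270")
#: schema-valid angles that break the equal-spacing protocol
OFF_PATTERN_ANGLES = ("45", "315")

TRUNC_SD = 4.0  # normal draws are truncated at +/- 4 sd


@dataclass
class ProtocolConfig:
    """Institutional protocol parameters used to draw normal plans."""

    imrt_mu_mean: float = 290.0
    tangent_mu_mean: float = 200.0
    mu_sd: float = 5.0
    ssd_mean: float = 100.0
    ssd_sd: float = 1.0
    jaw_means: dict = field(
        default_factory=lambda: {
            "collx1": 6.0,
            "collx2": 7.0,
            "colly1": 9.0,
            "colly2": 10.0,
        }
    )
    jaw_sd: float = 1.0
    jaw_position_ranges: dict = field(
        default_factory=lambda: {
            "collx1": (2.0, 10.0),
            "collx2": (3.0, 11.0),
            "colly1": (5.0, 13.0),
            "colly2": (6.0, 14.0),
        }
    )
    gantry_level_sets: tuple = (EQUAL_SPACING_PATTERN,)
    rotate_gantry_pattern: bool = False
    segment_range: tuple = (5, 7)
    continuous_noise_correlation: float = 0.9

    def __post_init__(self) -> None:
        if self.mu_sd <= 0 or self.ssd_sd <= 0 or self.jaw_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if not 0 <= self.continuous_noise_correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if self.segment_range[0] > self.segment_range[1]:
            raise ValueError("empty segment_range")


@dataclass(frozen=True)
class AnomalySpec:
    """One protocol-violation family, with effect size in feature sds."""

    type: str
    magnitude: float = 3.0
    n_features_perturbed: int = 1

    def __post_init__(self) -> None:
        if self.type not in ANOMALY_TYPES:
            raise ValueError(f"unknown anomaly type {self.type!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.n_features_perturbed < 1:
            raise ValueError("n_features_perturbed must be >= 1")


def default_anomaly_mix(magnitude: float = 3.0) -> list[tuple[AnomalySpec, float]]:
    """Uniform mix over the five single anomaly families."""
    singles = [t for t in ANOMALY_TYPES if t != "mixed"]
    w = 1.0 / len(singles)
    return [(AnomalySpec(t, magnitude=magnitude), w) for t in singles]


@dataclass
class GenConfig:
    """Dataset-level generation parameters (defaults mirror the benchmark)."""

    n_normal: int = 557
    n_abnormal: int = 19
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    anomaly_mix: list = field(default_factory=default_anomaly_mix)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("plan counts must be >= 0")
        total = sum(w for _, w in self.anomaly_mix)
        if self.n_abnormal > 0:
            if not self.anomaly_mix or total <= 0:
                raise ValueError("anomaly_mix must have positive total weight")
            if abs(total - 1.0) > 1e-9:
                self.anomaly_mix = [(s, w / total) for s, w in self.anomaly_mix]

    def hash(self) -> str:
        doc = asdict(self)
        payload = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _trunc_normal(rng: np.random.Generator, size=None) -> np.ndarray:
    """Standard normal draws truncated at +/- TRUNC_SD (by redraw)."""
    z = rng.normal(size=size)
    bad = np.abs(z) > TRUNC_SD
    while np.any(bad):
        z = np.where(bad, rng.normal(size=size), z)
        bad = np.abs(z) > TRUNC_SD
    return z


_JAWS = ("collx1", "collx2", "colly1", "colly2")


def generate_normal_plan(
    protocol: ProtocolConfig, rng: np.random.Generator
) -> PlanRecord:
    """Draw one protocol-conforming plan record for the default schema.

    Jaw positions share a per-field latent factor with the configured
    correlation; gantry angles are a random assignment of the
    equally-spaced beam pattern; MU and SSD are truncated normals around
    the protocol means.
    """
    p = protocol
    values: dict[str, object] = {}

    # shared per-plan geometry factor: couples SSD, jaws and MU so normal
    # plans live near a low-dimensional manifold a reconstruction model can fit
    rho = p.continuous_noise_correlation
    sq, sr = np.sqrt(rho), np.sqrt(1.0 - rho)
    u = float(_trunc_normal(rng))

    def draw_z() -> float:
        # unit-variance draw with loading sqrt(rho) on the plan factor,
        # clipped so marginals stay within +/- TRUNC_SD feature sds
        z = sq * u + sr * float(_trunc_normal(rng))
        return float(np.clip(z, -TRUNC_SD, TRUNC_SD))

    # segments (IMRT fields only), inside the protocol range
    lo, hi = p.segment_range
    for f in (1, 2):
        values[f"segment_f{f}"] = str(int(rng.integers(lo, hi + 1)))

    # SSD per field
    for f in range(1, 5):
        values[f"ssd_f{f}"] = p.ssd_mean + p.ssd_sd * draw_z()

    # jaw positions
    for f in range(1, 5):
        for jaw in _JAWS:
            val = p.jaw_means[jaw] + p.jaw_sd * draw_z()
            lo_j, hi_j = p.jaw_position_ranges[jaw]
            values[f"{jaw}_f{f}"] = float(np.clip(val, lo_j, hi_j))

    # gantry: one equally-spaced pattern, optionally rotated; fixed
    # arrangements keep normal plans low-entropy enough to reconstruct
    pattern = list(p.gantry_level_sets[int(rng.integers(len(p.gantry_level_sets)))])
    if p.rotate_gantry_pattern:
        k = int(rng.integers(len(pattern)))
        pattern = pattern[k:] + pattern[:k]
    for f, angle in zip(range(1, 5), pattern):
        values[f"gantry_f{f}"] = angle

    # monitor units: IMRT fields then tangent fields
    for f in range(1, 5):
        mean = p.imrt_mu_mean if (f - 1) in IMRT_FIELDS else p.tangent_mu_mean
        values[f"meterset_f{f}"] = mean + p.mu_sd * draw_z()

    schema = default_schema()
    ordered = tuple(values[c] for c in schema.column_names())
    return validate_record(schema, ordered)


def _set(values: list, cols: list[str], name: str, value) -> None:
    values[cols.index(name)] = value


def inject_anomaly(
    record: PlanRecord,
    spec: AnomalySpec,
    rng: np.random.Generator,
    protocol: ProtocolConfig | None = None,
) -> PlanRecord:
    """Perturb a normal record into a schema-valid protocol violation."""
    if protocol is None:
        protocol = ProtocolConfig()
    schema = default_schema()
    cols = schema.column_names()
    values = list(record.values)

    def apply_one(kind: str) -> None:
        if kind == "mu_offset":
            f = int(rng.integers(1, 5))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            col = f"meterset_f{f}"
            _set(values, cols, col, values[cols.index(col)]
                 + sign * spec.magnitude * protocol.mu_sd)
        elif kind == "unequal_beam_spacing":
            f = int(rng.integers(1, 5))
            angle = OFF_PATTERN_ANGLES[int(rng.integers(len(OFF_PATTERN_ANGLES)))]
            _set(values, cols, f"gantry_f{f}", angle)
        elif kind == "jaw_asymmetry":
            jaw = _JAWS[int(rng.integers(len(_JAWS)))]
            f = int(rng.integers(1, 5))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            col = f"{jaw}_f{f}"
            _set(values, cols, col, values[cols.index(col)]
                 + sign * spec.magnitude * protocol.jaw_sd)
        elif kind == "segment_count_violation":
            f = int(rng.integers(1, 3))
            lo, hi = protocol.segment_range
            seg_spec = schema.spec_for_column("segment_f1")
            outside = [l for l in seg_spec.levels if not lo <= int(l) <= hi]
            if not outside:
                raise ValueError("no schema level outside the protocol segment range")
            _set(values, cols, f"segment_f{f}",
                 outside[int(rng.integers(len(outside)))])
        elif kind == "ssd_outlier":
            f = int(rng.integers(1, 5))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            col = f"ssd_f{f}"
            _set(values, cols, col, values[cols.index(col)]
                 + sign * spec.magnitude * protocol.ssd_sd)
        else:  # mixed: two distinct single families
            singles = [t for t in ANOMALY_TYPES if t != "mixed"]
            picks = rng.choice(len(singles), size=2, replace=False)
            for k in picks:
                apply_one(singles[int(k)])

    for _ in range(spec.n_features_perturbed):
        apply_one(spec.type)
    out = validate_record(schema, tuple(values))
    if out.values == record.values:
        # extremely unlikely (cancelling perturbations); force a MU shift
        apply_one("mu_offset")
        out = validate_record(schema, tuple(values))
    return out


def generate_dataset(config: GenConfig) -> tuple[PlanTable, dict]:
    """Generate a labeled, shuffled plan table plus a provenance manifest."""
    rng = np.random.default_rng(config.seed)
    records: list[PlanRecord] = []
    labels: list[str] = []
    counts: dict[str, int] = {}

    for _ in range(config.n_normal):
        records.append(generate_normal_plan(config.protocol, rng))
        labels.append(NORMAL_LABEL)

    specs = [s for s, _ in config.anomaly_mix]
    weights = np.array([w for _, w in config.anomaly_mix], dtype=float)
    for _ in range(config.n_abnormal):
        base = generate_normal_plan(config.protocol, rng)
        k = int(rng.choice(len(specs), p=weights))
        spec = specs[k]
        records.append(inject_anomaly(base, spec, rng, config.protocol))
        labels.append(ABNORMAL_LABEL)
        counts[spec.type] = counts.get(spec.type, 0) + 1

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    labels = [labels[i] for i in order]
    ids = [f"plan_{i + 1:04d}" for i in range(len(records))]

    table = PlanTable(schema=default_schema(), records=records, labels=labels, ids=ids)
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_normal": config.n_normal,
        "n_abnormal": config.n_abnormal,
        "anomaly_counts": counts,
    }
    return table, manifest


def write_dataset(table: PlanTable, manifest: dict, outdir: str | Path) -> None:
    """Write the CSV dialect plus a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "plans.csv")
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def _equal_circular_spacing(angles: list[int]) -> bool:
    a = np.sort(np.asarray(angles) % 360)
    gaps = np.diff(np.concatenate([a, [a[0] + 360]]))
    return bool(np.all(gaps == gaps[0]))


def protocol_violations(record: PlanRecord, protocol: ProtocolConfig) -> list[str]:
    """Names of protocol predicates the record violates (empty for normals)."""
    schema = default_schema()
    cols = schema.column_names()
    v = dict(zip(cols, record.values))
    out = []

    lo, hi = protocol.segment_range
    if not all(lo <= int(v[f"segment_f{f}"]) <= hi for f in (1, 2)):
        out.append("segments_in_range")

    angles = [int(v[f"gantry_f{f}"]) for f in range(1, 5)]
    if not _equal_circular_spacing(angles):
        out.append("equal_beam_spacing")

    for f in range(1, 5):
        mean = (
            protocol.imrt_mu_mean if (f - 1) in IMRT_FIELDS else protocol.tangent_mu_mean
        )
        if abs(v[f"meterset_f{f}"] - mean) > TRUNC_SD * protocol.mu_sd + 1e-9:
            out.append("mu_within_4sd")
            break

    for f in range(1, 5):
        if abs(v[f"ssd_f{f}"] - protocol.ssd_mean) > TRUNC_SD * protocol.ssd_sd + 1e-9:
            out.append("ssd_within_4sd")
            break

    for jaw in _JAWS:
        lo_j, hi_j = protocol.jaw_position_ranges[jaw]
        if not all(lo_j <= v[f"{jaw}_f{f}"] <= hi_j for f in range(1, 5)):
            out.append("jaws_in_range")
            break
    return out
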