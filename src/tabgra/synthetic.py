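"""Synthetic food-safety detection datasets.

Emulates the record structure of provincial cooked-meat surveillance data:
nine risk indicators (three additives, four heavy metals, two microbial
counts), per-indicator regulatory limits and assay detection limits,
left-censored results ("<0.005"), "Not Detected" entries, and replicate
plate counts ("80; 70; 90; 50; 180").  Contamination levels follow a
log-normal model whose median hazard quotient is configurable (default
0.1), with sporadic exceedances injected at a fixed per-cell probability.
Every dataset carries the ground-truth clean matrix and its GRA composite
risks, so the parsing, weighting and regression modules are all testable
without any external download.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .detection_io import (
    DetectionMatrix,
    IndicatorSpec,
    RawRecord,
)
from .gra import GRAConfig, GRAResult, compute_risk

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "default_indicator_specs",
    "DEFAULT_COUNT_INDICATORS",
    "simulate_dataset",
    "rawify",
    "write_raw_csv",
]


def default_indicator_specs() -> list[IndicatorSpec]:
    """The nine-indicator system for cooked meat products.

    Limits: heavy metals and nitrite in mg/kg, preservatives in g/kg,
    microbial counts in CFU/g.  Benzoic acid is not permitted at all in
    these products, so its hazard denominator falls back to the assay
    detection limit.
    """
    return [
        IndicatorSpec("lead", 0.5, 0.05, "mg/kg"),
        IndicatorSpec("cadmium", 0.1, 0.003, "mg/kg"),
        IndicatorSpec("chromium", 1.0, 0.03, "mg/kg"),
        IndicatorSpec("total arsenic", 0.5, 0.04, "mg/kg"),
        IndicatorSpec("nitrite", 30.0, 0.2, "mg/kg"),
        IndicatorSpec("sorbic acid", 0.075, 0.01, "g/kg"),
        IndicatorSpec("benzoic acid", 0.005, 0.005, "g/kg", "not-permitted-fallback"),
        IndicatorSpec("total bacterial count", 10000.0, None, "CFU/g"),
        IndicatorSpec("coliform group", 10.0, None, "CFU/g"),
    ]


DEFAULT_COUNT_INDICATORS = frozenset({"total bacterial count", "coliform group"})

_PRODUCTS = ["Duck in sauce", "Beef Jerky", "Ham Sausage", "Bacon", "Roasted leg with sauce"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the simulated surveillance campaign.

    ``median_hq`` sets the log-normal location so the median hazard quotient
    of an in-control cell is about 0.1 of the limit; ``sigma`` is the
    log-scale spread.  ``exceedance_prob`` is the per-cell probability of an
    out-of-limit value; ``nondetect_prob`` the probability an assay reports
    "Not Detected" (imputed downstream at half the detection limit);
    ``multi_value_prob`` the probability a count indicator reports
    ``n_replicates`` plate counts reduced to their maximum.
    """

    n_samples: int = 100
    indicator_specs: tuple[IndicatorSpec, ...] = field(
        default_factory=lambda: tuple(default_indicator_specs())
    )
    count_indicators: frozenset[str] = DEFAULT_COUNT_INDICATORS
    median_hq: float = 0.1
    sigma: float = 0.8
    exceedance_prob: float = 0.03
    nondetect_prob: float = 0.15
    multi_value_prob: float = 0.3
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2 (GRA needs at least 2 samples)")
        if not self.indicator_specs:
            raise ValueError("at least one indicator is required")
        for p in (self.exceedance_prob, self.nondetect_prob, self.multi_value_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma <= 0 or self.median_hq <= 0:
            raise ValueError("sigma and median_hq must be positive")


@dataclass
class SyntheticDataset:
    """Raw records, their ground-truth clean matrix, and GRA composite risks."""

    raw_records: list[RawRecord]
    clean_matrix: DetectionMatrix
    true_risks: np.ndarray
    gra: GRAResult


def _is_count(spec: IndicatorSpec, cfg: GeneratorConfig) -> bool:
    return spec.name in cfg.count_indicators


def _fmt(value: float, spec: IndicatorSpec, cfg: GeneratorConfig) -> str:
    """Render a clean value the way the source tables print it."""
    if _is_count(spec, cfg):
        return str(int(round(value)))
    return f"{value:.4f}"


def rawify(
    value: float,
    spec: IndicatorSpec,
    style: str,
    rng: np.random.Generator,
    *,
    cfg: GeneratorConfig | None = None,
    n_replicates: int = 5,
) -> str:
    """Render a clean value back into a raw detection-result string.

    ``style`` is one of plain / censored / not-detected / multi.  The
    censored style renders "<bound" where the bound equals the clean value
    (parsing strips the "<" back to the bound); not-detected requires the
    clean value to be exactly half the detection limit; multi emits
    replicate counts whose maximum is the clean value.
    """
    cfg = cfg or GeneratorConfig()
    if style == "plain":
        return _fmt(value, spec, cfg)
    if style == "censored":
        if spec.detection_limit is None or value > spec.detection_limit:
            raise ValueError(
                f"censored style needs a clean value at/below the detection limit "
                f"of {spec.name!r}"
            )
        return "<" + _fmt(value, spec, cfg)
    if style == "not-detected":
        if spec.detection_limit is None or value != spec.detection_limit / 2.0:
            raise ValueError(
                "not-detected style requires clean value == detection_limit / 2"
            )
        return "Not Detected"
    if style == "multi":
        top = int(round(value))
        lo = max(0, int(top * 0.2))
        others = rng.integers(lo, max(top, 1), size=max(0, n_replicates - 1))
        counts = np.append(others, top)
        rng.shuffle(counts)
        return "; ".join(str(int(c)) for c in counts)
    raise ValueError(f"unknown rawify style {style!r}")


def _draw_cell(
    spec: IndicatorSpec, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[float, str]:
    """One (clean value, style) draw for a single sample x indicator cell."""
    limit = spec.max_limit
    is_count = _is_count(spec, cfg)
    u = rng.random()
    if u < cfg.exceedance_prob:
        value = limit * rng.uniform(1.05, 3.0)
        style = "plain"
    elif spec.detection_limit is not None and u < cfg.exceedance_prob + cfg.nondetect_prob:
        return spec.detection_limit / 2.0, "not-detected"
    else:
        # in-control draw: log-normal with median at median_hq * limit,
        # truncated at the limit so only injected exceedances cross it
        value = min(rng.lognormal(np.log(cfg.median_hq * limit), cfg.sigma), limit)
        style = "plain"
        if spec.detection_limit is not None and value < spec.detection_limit:
            # below the assay floor: reported as "<LOD", parsed back to the bound
            return spec.detection_limit, "censored"
    if is_count and rng.random() < cfg.multi_value_prob:
        style = "multi"
    # the clean value is exactly what the rendered string parses back to
    value = float(_fmt(value, spec, cfg))
    return value, style


def simulate_dataset(
    cfg: GeneratorConfig = GeneratorConfig(), gra_cfg: GRAConfig = GRAConfig()
) -> SyntheticDataset:
    """Draw a full synthetic surveillance dataset, reproducible under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    specs = list(cfg.indicator_specs)
    n, m = cfg.n_samples, len(specs)
    values = np.zeros((n, m))
    records: list[RawRecord] = []
    start = datetime.date(2018, 1, 3)
    record_no = 0
    samples = [str(k + 1) for k in range(n)]
    for k in range(n):
        day = start + datetime.timedelta(days=k // 4)
        product = _PRODUCTS[k % len(_PRODUCTS)]
        for i, spec in enumerate(specs):
            value, style = _draw_cell(spec, cfg, rng)
            values[k, i] = value
            result = rawify(value, spec, style, rng, cfg=cfg,
                            n_replicates=cfg.n_replicates)
            limit_text = ("shall not be used"
                          if spec.limit_source == "not-permitted-fallback"
                          else f"{spec.max_limit:g}")
            record_no += 1
            records.append(
                RawRecord(
                    record_no=record_no,
                    sample_no=samples[k],
                    sampling_time=day.isoformat(),
                    product_name=product,
                    detection_item=spec.name,
                    detection_result=result,
                    maximum_limit=limit_text,
                    standard_detection_limit=spec.detection_limit,
                    unit=spec.unit,
                )
            )
    matrix = DetectionMatrix(samples, specs, values)
    gra = compute_risk(matrix, gra_cfg)
    return SyntheticDataset(records, matrix, gra.risks, gra)


def write_raw_csv(records: list[RawRecord], path: str) -> None:
    """Write raw records in the canonical raw-table schema."""
    import pandas as pd

    pd.DataFrame(
        {
            "record_no": [r.record_no for r in records],
            "sample_no": [r.sample_no for r in records],
            "sampling_time": [r.sampling_time for r in records],
            "product_name": [r.product_name for r in records],
            "detection_item": [r.detection_item for r in records],
            "detection_result": [r.detection_result for r in records],
            "maximum_limit": [r.maximum_limit for r in records],
            "standard_detection_limit": [
                "" if r.standard_detection_limit is None else f"{r.standard_detection_limit:g}"
                for r in records
            ],
            "unit": [r.unit for r in records],
        }
    ).to_csv(path, index=False)
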