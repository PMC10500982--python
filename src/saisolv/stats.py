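"""Benchmark statistics for computed vs experimental solvation free energies.

Works on FreeSolv-style delimited flat files (semicolon-separated, ``#``
comment lines, one compound per row with experimental and calculated
hydration free energies in kcal/mol).  Provides the usual error metrics
(RMSE, MAE, Pearson r, Spearman rho) with nonparametric bootstrap
confidence intervals (molecule-level resampling, percentile method),
deviation-count tables, per-functional-group summaries, and per-size
(heavy-atom-count) error profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .errors import ParseError, ValidationError

#: column index of each field in a FreeSolv-style file (configurable
#: because the upstream column layout has changed across releases)
DEFAULT_COLUMNS = {
    "compound_id": 0,
    "smiles": 1,
    "name": 2,
    "expt": 3,
    "expt_unc": 4,
    "calc": 5,
    "calc_unc": 6,
}

DEFAULT_THRESHOLDS = (2.0, 3.0, 4.0, 6.0)  # kcal/mol
MIN_GROUP_SIZE = 10
BOOTSTRAP_DEFAULT_B = 10_000


@dataclass
class FreeSolvRecord:
    compound_id: str
    smiles: str
    name: str
    expt: float          # kcal/mol
    expt_unc: float
    calc: float
    calc_unc: float
    group: str | None = None
    heavy_atoms: int | None = None

    def __post_init__(self):
        if not (math.isfinite(self.expt) and math.isfinite(self.calc)):
            raise ValidationError(
                f"{self.compound_id}: expt and calc must be finite")
        if self.expt_unc < 0 or self.calc_unc < 0:
            raise ValidationError(
                f"{self.compound_id}: uncertainties must be >= 0")


@dataclass
class MetricReport:
    rmse: float
    mae: float
    pearson_r: float
    spearman_rho: float
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def parse_freesolv(path, delimiter: str = ";",
                   columns: dict[str, int] | None = None) -> list[FreeSolvRecord]:
    """Parse a FreeSolv-style delimited file into records.

    Lines starting with '#' are comments; malformed data lines raise a
    :class:`ParseError` naming the line number.
    """
    columns = columns or DEFAULT_COLUMNS
    needed = max(columns.values()) + 1
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < needed:
                raise ParseError(
                    f"expected at least {needed} columns, got {len(fields)}",
                    line=lineno)
            try:
                records.append(FreeSolvRecord(
                    compound_id=fields[columns["compound_id"]],
                    smiles=fields[columns["smiles"]],
                    name=fields[columns["name"]],
                    expt=float(fields[columns["expt"]]),
                    expt_unc=float(fields[columns["expt_unc"]]),
                    calc=float(fields[columns["calc"]]),
                    calc_unc=float(fields[columns["calc_unc"]]),
                ))
            except ValueError as exc:
                raise ParseError(f"numeric field: {exc}", line=lineno) from exc
    return records


def attach_groups(records: list[FreeSolvRecord], groups_path,
                  delimiter: str = ";") -> None:
    """Assign each record its *first* listed functional-group category.

    The groups file maps compound id -> a delimited list of categories;
    polyfunctional compounds are assigned only the first category to avoid
    double counting.
    """
    table: dict[str, str] = {}
    with open(groups_path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) >= 2 and fields[1]:
                table[fields[0]] = fields[1].split(",")[0].strip()
    for rec in records:
        rec.group = table.get(rec.compound_id)


def deviation(calc: float, expt: float) -> tuple[float, float]:
    """(signed, absolute) deviation of a calculated value from experiment."""
    signed = calc - expt
    return signed, abs(signed)


def _signed_deviations(records) -> np.ndarray:
    return np.array([r.calc - r.expt for r in records])


def _rmse(calc, expt):
    d = calc - expt
    return float(np.sqrt(np.mean(d * d)))


def _mae(calc, expt):
    return float(np.mean(np.abs(calc - expt)))


def _pearson(calc, expt):
    if np.ptp(calc) == 0 or np.ptp(expt) == 0:
        raise ValidationError("correlation undefined for constant vectors")
    return float(pearsonr(calc, expt)[0])


def _spearman(calc, expt):
    if np.ptp(calc) == 0 or np.ptp(expt) == 0:
        raise ValidationError("correlation undefined for constant vectors")
    return float(spearmanr(calc, expt)[0])  # average-rank ties


METRIC_FUNCTIONS = {"rmse": _rmse, "mae": _mae, "pearson_r": _pearson,
                    "spearman_rho": _spearman}
METRIC_NAMES = tuple(METRIC_FUNCTIONS)


def error_metrics(records: list[FreeSolvRecord],
                  bootstrap_b: int | None = None,
                  seed: int = 0,
                  correlations: bool = True) -> MetricReport:
    """RMSE, MAE, Pearson r and Spearman rho of calc vs expt.

    Constant calc or expt vectors make the correlations undefined and
    raise; pass ``correlations=False`` to get the deviation metrics alone
    (the correlation fields are then NaN).  With ``bootstrap_b`` set, 95%
    percentile bootstrap intervals are attached for every metric computed.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records")
    calc = np.array([r.calc for r in records])
    expt = np.array([r.expt for r in records])
    vals = {"rmse": _rmse(calc, expt), "mae": _mae(calc, expt)}
    if correlations:
        vals["pearson_r"] = _pearson(calc, expt)
        vals["spearman_rho"] = _spearman(calc, expt)
    else:
        vals["pearson_r"] = vals["spearman_rho"] = float("nan")
    ci = {}
    if bootstrap_b:
        names = METRIC_NAMES if correlations else ("rmse", "mae")
        for name in names:
            ci[name] = bootstrap_ci(records, name, b=bootstrap_b, seed=seed)
    return MetricReport(n=len(records), ci=ci, **vals)


def bootstrap_ci(records: list[FreeSolvRecord], metric,
                 b: int = BOOTSTRAP_DEFAULT_B, seed: int = 0,
                 levels: tuple[float, float] = (2.5, 97.5)) -> tuple[float, float]:
    """Nonparametric bootstrap percentile interval for one metric.

    Molecules are resampled with replacement ``b`` times; ``metric`` is a
    metric name from :data:`METRIC_NAMES` or a callable
    ``f(calc, expt) -> float``.  A fixed seed makes the interval
    reproducible.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records")
    if callable(metric):
        fn = metric
    else:
        name = str(metric)
        if name not in METRIC_FUNCTIONS:
            raise ValidationError(f"unknown metric {name!r}")
        fn = METRIC_FUNCTIONS[name]
    calc = np.array([r.calc for r in records])
    expt = np.array([r.expt for r in records])
    rng = np.random.default_rng(seed)
    n = len(records)
    stats = []
    for _ in range(int(b)):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(fn(calc[idx], expt[idx]))
        except ValidationError:
            continue  # degenerate resample (constant vector)
    if not stats:
        raise ValidationError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(stats, levels)
    return float(lo), float(hi)


def deviation_counts(records: list[FreeSolvRecord],
                     thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Number (and percentage) of molecules whose absolute deviation from
    experiment exceeds each threshold."""
    abs_dev = np.abs(_signed_deviations(records))
    n = len(records)
    rows = []
    for t in thresholds:
        count = int(np.sum(abs_dev > t))
        rows.append({"threshold": float(t), "count": count,
                     "percent": 100.0 * count / n if n else 0.0})
    return pd.DataFrame(rows)


def group_summary(records: list[FreeSolvRecord],
                  min_group_size: int = MIN_GROUP_SIZE
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Per-functional-group absolute-error summary.

    Groups with fewer than ``min_group_size`` members are excluded from the
    table and returned in the below-threshold list instead.
    """
    by_group: dict[str, list[float]] = {}
    for rec in records:
        if rec.group:
            by_group.setdefault(rec.group, []).append(abs(rec.calc - rec.expt))
    rows = []
    below = []
    for group in sorted(by_group):
        devs = np.array(by_group[group])
        if devs.size < min_group_size:
            below.append(group)
            continue
        q1, med, q3 = np.percentile(devs, [25, 50, 75])
        rows.append({"group": group, "n": int(devs.size),
                     "mae": float(devs.mean()),
                     "median_ae": float(med),
                     "q1": float(q1), "q3": float(q3),
                     "min": float(devs.min()), "max": float(devs.max())})
    return pd.DataFrame(rows), below


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms (halogens included) in a SMILES string."""
    from rdkit import Chem  # deferred: only needed for size binning
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparsable SMILES {smiles!r}")
    return mol.GetNumHeavyAtoms()


def error_by_size(records: list[FreeSolvRecord],
                  bootstrap_b: int = 1000, seed: int = 0) -> pd.DataFrame:
    """MAE per heavy-atom-count bin with bootstrap bands.

    Heavy-atom counts are taken from ``record.heavy_atoms`` when present
    and otherwise derived from the SMILES string.  Bins holding a single
    molecule are reported without a band.
    """
    rng = np.random.default_rng(seed)
    bins: dict[int, list[float]] = {}
    for rec in records:
        count = rec.heavy_atoms
        if count is None:
            count = heavy_atom_count(rec.smiles)
        bins.setdefault(int(count), []).append(abs(rec.calc - rec.expt))
    rows = []
    for size in sorted(bins):
        devs = np.array(bins[size])
        row = {"heavy_atoms": size, "n": int(devs.size),
               "mae": float(devs.mean()),
               "ci_low": float("nan"), "ci_high": float("nan")}
        if devs.size > 1 and bootstrap_b:
            maes = [float(np.mean(devs[rng.integers(0, devs.size,
                                                    size=devs.size)]))
                    for _ in range(int(bootstrap_b))]
            row["ci_low"], row["ci_high"] = (
                float(v) for v in np.percentile(maes, [2.5, 97.5]))
        rows.append(row)
    return pd.DataFrame(rows)
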