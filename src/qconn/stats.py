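"""Comparison statistics for connection counts across encoding schemes.

The central quantity is the *normalized connectivity*: a scan's connection
count divided by the per-subject mean count of the reference scans (the
three repeated full-lattice DSI acquisitions).  Around it sit paired
t-tests with Bonferroni correction, scan-rescan vs inter-subject
variability, fiber limitation (random subsampling of every scheme's fiber
set to the per-subject minimum F_s before matrix construction), and
distance-binned connection tables.

Replicate columns of the reference scheme are written ``NAME(1)``,
``NAME(2)``, ... — the convention used throughout for scan-rescan data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import ConnectionMatrix, DistanceMatrix, count_connections, distance_distribution
from .tracking import StreamlineSet

__all__ = [
    "SchemeRunResult",
    "ComparisonReport",
    "load_connection_table",
    "normalized_connectivity",
    "fiber_limitation",
    "paired_t_test",
    "bonferroni",
    "variability",
    "spread_across_replicates",
    "compare_report",
]

_REPLICATE_RE = re.compile(r"^(?P<scheme>.+)\((?P<rep>\d+)\)$")


@dataclass
class SchemeRunResult:
    """Connection count of one scheme on one subject (one scan)."""

    scheme: str  # base scheme name, e.g. "DSIq5b8000"
    subject: str | int
    connection_count: int
    replicate: int = 1
    fiber_count: int | None = None
    matrix: ConnectionMatrix | None = None
    distances: DistanceMatrix | None = None
    streamlines: StreamlineSet | None = None

    @property
    def column(self) -> str:
        return f"{self.scheme}({self.replicate})" if self.replicate else self.scheme


@dataclass
class ComparisonReport:
    normalized: pd.DataFrame  # subject x scan column, ratios
    mean_normalized: pd.Series  # per scan column, averaged over subjects
    paired_tests: pd.DataFrame  # one row per scan-column pair
    variability_scan_rescan: float
    variability_inter_subject: float
    max_replicate_spread: float
    distance_bins: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def load_connection_table(path=None) -> pd.DataFrame:
    """Connection-count table, rows = subjects, columns = scans.

    With no path, loads the packaged whole-brain table for the five
    subjects and eight scans of the reference acquisition protocol.
    """
    if path is None:
        ref = resources.files("qconn.data") / "table2_connections.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, index_col="subject")
    return pd.read_csv(path, index_col="subject")


def split_scheme_column(col: str) -> tuple[str, int]:
    m = _REPLICATE_RE.match(col)
    if m:
        return m.group("scheme"), int(m.group("rep"))
    return col, 1


def reference_columns(table: pd.DataFrame, reference: str) -> list[str]:
    cols = [c for c in table.columns if split_scheme_column(c)[0] == reference]
    if not cols:
        raise ValueError(f"reference scheme {reference!r} not among {list(table.columns)}")
    return cols


def normalized_connectivity(count: float, ref_counts) -> float:
    """count / mean(reference counts)."""
    ref = np.asarray(ref_counts, dtype=float)
    if ref.size == 0 or np.any(ref <= 0):
        raise ValueError("reference counts must be nonempty and positive")
    return float(count) / float(ref.mean())


def fiber_limitation(sets: dict, rng_seed: int = 0) -> dict:
    """Subsample every scheme's fiber set to the common minimum F_s.

    F_s is the minimum fiber count across schemes for this subject; each
    set is replaced by a uniform without-replacement sample of exactly F_s
    fibers.  Deterministic for a given ``rng_seed``.
    """
    if len(sets) < 2:
        raise ValueError("fiber limitation needs at least two schemes")
    counts = {k: s.count for k, s in sets.items()}
    if any(c == 0 for c in counts.values()):
        empty = [k for k, c in counts.items() if c == 0]
        raise ValueError(f"empty fiber set(s): {empty}")
    f_s = min(counts.values())
    rng = np.random.default_rng(rng_seed)
    out = {}
    for key in sets:  # fixed iteration order -> deterministic draws
        s = sets[key]
        keep = np.sort(rng.choice(s.count, size=f_s, replace=False))
        out[key] = StreamlineSet(
            [s.streamlines[i] for i in keep],
            provenance=dict(s.provenance, fiber_limited_to=f_s),
            endpoint_labels=None if s.endpoint_labels is None
            else s.endpoint_labels[keep],
        )
    return out


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired Student t on the differences; two-sided p, df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1-D samples")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    if np.allclose(x, y):
        return 0.0, len(x) - 1, 1.0
    res = sps.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def bonferroni(p_values, m: int) -> list[float]:
    """min(1, p * m) per value; ``m`` = number of tests in the family."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = list(p_values)
    if m < len(p):
        raise ValueError(f"m = {m} smaller than the {len(p)} tests supplied")
    return [min(1.0, v * m) for v in p]


def variability(counts: pd.DataFrame) -> tuple[float, float]:
    """(scan-rescan sigma, inter-subject sigma) of a replicate x subject table.

    ``counts``: rows = subjects, columns = replicates of one scheme.
    Scan-rescan: mean over subjects of the per-subject sample SD (n-1)
    across replicates.  Inter-subject: mean over replicates of the sample
    SD across subjects.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two replicates per subject")
    scan_rescan = float(counts.std(axis=1, ddof=1).mean())
    inter_subject = float(counts.std(axis=0, ddof=1).mean())
    return scan_rescan, inter_subject


def spread_across_replicates(counts: pd.DataFrame) -> float:
    """Max over subjects of (max - min) of mean-normalized replicate counts."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two replicates per subject")
    normed = counts.div(counts.mean(axis=1), axis=0)
    return float((normed.max(axis=1) - normed.min(axis=1)).max())


def _runs_to_table(runs) -> pd.DataFrame:
    rows = {}
    for r in runs:
        rows.setdefault(r.subject, {})[r.column] = r.connection_count
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise ValueError(f"incomplete design: missing counts for {missing}")
    return table


def compare_report(
    runs,
    reference: str,
    n_f: int = 1,
    bins=(0.0, 50.0, 100.0, 200.0),
    rng_seed: int = 0,
) -> ComparisonReport:
    """Assemble the full comparison from per-scan results or a count table.

    ``runs`` is either a list of SchemeRunResult or a subjects x scans
    DataFrame (replicates of the reference named ``scheme(k)``).  The
    normalized table divides each scan's count by the per-subject mean of
    the reference replicates, so reference scans average to exactly 1 per
    subject.  All pairwise paired t-tests are Bonferroni-corrected over the
    number of scan pairs.
    """
    if isinstance(runs, pd.DataFrame):
        table = runs.copy()
        run_list = []
    else:
        run_list = list(runs)
        table = _runs_to_table(run_list)
    ref_cols = reference_columns(table, reference)
    ref_mean = table[ref_cols].mean(axis=1)
    normalized = table.div(ref_mean, axis=0)
    mean_normalized = normalized.mean(axis=0)

    pairs = list(combinations(table.columns, 2))
    rows = []
    for a, b in pairs:
        t, df, p = paired_t_test(table[a].to_numpy(), table[b].to_numpy())
        rows.append({"scan_a": a, "scan_b": b, "t": t, "df": df, "p": p})
    tests = pd.DataFrame(rows)
    tests["p_bonferroni"] = bonferroni(tests["p"].tolist(), m=len(pairs))

    sigma_rescan, sigma_subject = variability(table[ref_cols])
    spread = spread_across_replicates(table[ref_cols])

    distance_bins = None
    if run_list and all(
        r.matrix is not None and r.distances is not None for r in run_list
    ):
        rows = []
        for r in run_list:
            counts, unreach = distance_distribution(r.matrix, r.distances, bins, n_f=n_f)
            rows.append(
                {"scan": r.column, "subject": r.subject,
                 **{f"{int(lo)}-{int(hi)}mm": c
                    for lo, hi, c in zip(bins[:-1], bins[1:], counts)},
                 "unreachable": unreach}
            )
        distance_bins = pd.DataFrame(rows)

    return ComparisonReport(
        normalized=normalized,
        mean_normalized=mean_normalized,
        paired_tests=tests,
        variability_scan_rescan=sigma_rescan,
        variability_inter_subject=sigma_subject,
        max_replicate_spread=spread,
        distance_bins=distance_bins,
        provenance={"reference": reference, "n_f": n_f, "bins": tuple(bins),
                    "rng_seed": rng_seed},
    )
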