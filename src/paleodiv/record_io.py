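"""Reading, validation and writing of sediment-record tables.

A site record is a CSV triplet (plus an optional taxon-group table):

``counts.csv``
    one row per sediment sample, ``sample_id`` column plus one column per
    taxon holding non-negative (possibly non-integer) counts.
``meta.csv``
    ``sample_id, depth_top_cm, depth_bottom_cm, volume_cm3``.
``agedepth.csv``
    ``depth_cm, age_calBP`` control points of the age–depth model.
``groups.csv`` (optional)
    ``taxon, group`` with group one of tree / shrub / herb / other.

Depths are cm below the sediment surface; ages are calibrated years before
present (present = AD 1950) and increase with depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("tree", "shrub", "herb", "other")


class RecordValidationError(ValueError):
    """An input table violates the record contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeDepthModel:
    """Monotone piecewise-linear depth -> age mapping from control points.

    Parameters
    ----------
    depths : array of float
        Control-point depths in cm, strictly increasing.
    ages : array of float
        Calibrated ages (cal BP) at those depths, strictly increasing
        (deeper sediment is older).
    """

    depths: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        a = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "ages", a)
        if d.ndim != 1 or a.ndim != 1 or d.size != a.size:
            raise RecordValidationError("depths and ages must be equal-length 1-d arrays")
        if d.size < 2:
            raise RecordValidationError("age-depth model needs at least 2 control points")
        if not np.all(np.diff(d) > 0):
            raise RecordValidationError("control-point depths must be strictly increasing")
        if not np.all(np.diff(a) > 0):
            raise RecordValidationError(
                "ages must strictly increase with depth (age reversal in control points)"
            )

    @property
    def control_points(self) -> list[tuple[float, float]]:
        return list(zip(self.depths.tolist(), self.ages.tolist()))

    def age_at(self, depth):
        """Interpolate age (cal BP) at ``depth`` (cm); no extrapolation."""
        depth = np.asarray(depth, dtype=float)
        tol = 1e-9 * max(1.0, float(self.depths[-1]))
        if np.any(depth < self.depths[0] - tol) or np.any(depth > self.depths[-1] + tol):
            raise ValueError(
                f"depth outside age-depth model range "
                f"[{self.depths[0]}, {self.depths[-1]}] cm; refusing to extrapolate"
            )
        return np.interp(depth, self.depths, self.ages)

    def depth_at(self, age):
        """Inverse mapping: depth (cm) at ``age`` (cal BP); no extrapolation."""
        age = np.asarray(age, dtype=float)
        tol = 1e-9 * max(1.0, float(self.ages[-1]))
        if np.any(age < self.ages[0] - tol) or np.any(age > self.ages[-1] + tol):
            raise ValueError(
                f"age outside age-depth model range "
                f"[{self.ages[0]}, {self.ages[-1]}] cal BP; refusing to extrapolate"
            )
        return np.interp(age, self.ages, self.depths)


@dataclass
class SampleSeries:
    """An irregular series of sediment samples with per-taxon counts.

    Attributes
    ----------
    counts : pandas.DataFrame
        samples x taxa, indexed by sample id, non-negative values.
    depth_top, depth_bottom : arrays, cm
        Per-sample depth interval; samples are ordered top-down and must
        not overlap.
    volume : array, cm^3
        Per-sample sediment volume.
    groups : pandas.Series
        taxon -> functional group (tree / shrub / herb / other).
    """

    counts: pd.DataFrame
    depth_top: np.ndarray
    depth_bottom: np.ndarray
    volume: np.ndarray
    groups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.depth_top = np.asarray(self.depth_top, dtype=float)
        self.depth_bottom = np.asarray(self.depth_bottom, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = len(self.counts)
        if not (len(self.depth_top) == len(self.depth_bottom) == len(self.volume) == n):
            raise RecordValidationError("metadata arrays must match the number of samples")
        if n == 0:
            raise RecordValidationError("record has no samples")
        if np.any(self.depth_top >= self.depth_bottom):
            bad = self.counts.index[self.depth_top >= self.depth_bottom].tolist()
            raise RecordValidationError(f"depth_top must be < depth_bottom; offending samples: {bad}")
        order = np.argsort(self.depth_top)
        if not np.all(order == np.arange(n)):
            raise RecordValidationError("samples must be ordered by increasing depth")
        if np.any(self.depth_bottom[:-1] > self.depth_top[1:] + 1e-12):
            i = int(np.argmax(self.depth_bottom[:-1] > self.depth_top[1:] + 1e-12))
            raise RecordValidationError(
                f"overlapping depth intervals: sample {self.counts.index[i]!r} "
                f"(bottom {self.depth_bottom[i]}) overlaps {self.counts.index[i + 1]!r} "
                f"(top {self.depth_top[i + 1]})"
            )
        if np.any(self.volume <= 0):
            bad = self.counts.index[self.volume <= 0].tolist()
            raise RecordValidationError(f"sample volume must be > 0; offending samples: {bad}")
        vals = self.counts.to_numpy(dtype=float)
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise RecordValidationError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"taxon {self.counts.columns[c]!r}"
            )
        if self.counts.shape[1] < 1:
            raise RecordValidationError("record must contain at least one taxon")
        if self.groups is None:
            self.groups = pd.Series("other", index=self.counts.columns, name="group")
        else:
            missing = [t for t in self.counts.columns if t not in self.groups.index]
            if missing:
                logger.warning("no group label for taxa %s; defaulting to 'other'", missing)
            self.groups = self.groups.reindex(self.counts.columns).fillna("other")
            bad = sorted(set(self.groups) - set(GROUPS))
            if bad:
                raise RecordValidationError(f"unknown functional groups: {bad}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_record(counts_path, meta_path, agedepth_path, groups_path=None):
    """Read and validate a CSV triplet into (SampleSeries, AgeDepthModel).

    Sample ids must match (as sets) between the counts and metadata tables;
    the metadata depth order defines the sample order. Taxa absent from the
    groups table default to group ``other`` with a logged warning.
    """
    counts = pd.read_csv(counts_path)
    meta = pd.read_csv(meta_path)
    agedepth = pd.read_csv(agedepth_path)

    for name, df, col in (("counts", counts, "sample_id"), ("meta", meta, "sample_id")):
        if col not in df.columns:
            raise RecordValidationError(f"{name} file lacks required column {col!r}")
    for col in ("depth_top_cm", "depth_bottom_cm", "volume_cm3"):
        if col not in meta.columns:
            raise RecordValidationError(f"meta file lacks required column {col!r}")
    for col in ("depth_cm", "age_calBP"):
        if col not in agedepth.columns:
            raise RecordValidationError(f"agedepth file lacks required column {col!r}")

    counts = counts.set_index("sample_id")
    meta = meta.set_index("sample_id")
    only_counts = sorted(set(counts.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(counts.index))
    if only_counts or only_meta:
        raise RecordValidationError(
            f"sample ids do not match between counts and metadata; "
            f"counts-only: {only_counts}, meta-only: {only_meta}"
        )

    meta = meta.sort_values("depth_top_cm")
    counts = counts.loc[meta.index]

    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(groups_path)
        if not {"taxon", "group"} <= set(gdf.columns):
            raise RecordValidationError("groups file must have columns 'taxon' and 'group'")
        groups = gdf.set_index("taxon")["group"]

    model = AgeDepthModel(
        depths=agedepth["depth_cm"].to_numpy(),
        ages=agedepth["age_calBP"].to_numpy(),
    )
    samples = SampleSeries(
        counts=counts.astype(float),
        depth_top=meta["depth_top_cm"].to_numpy(),
        depth_bottom=meta["depth_bottom_cm"].to_numpy(),
        volume=meta["volume_cm3"].to_numpy(),
        groups=groups,
    )
    return samples, model


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_record(samples: SampleSeries, model: AgeDepthModel, out_dir) -> dict:
    """Write a record back to the CSV triplet schema (plus groups.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "meta": out / "meta.csv",
        "agedepth": out / "agedepth.csv",
        "groups": out / "groups.csv",
    }
    samples.counts.rename_axis("sample_id").reset_index().to_csv(paths["counts"], index=False)
    pd.DataFrame(
        {
            "sample_id": samples.sample_ids,
            "depth_top_cm": samples.depth_top,
            "depth_bottom_cm": samples.depth_bottom,
            "volume_cm3": samples.volume,
        }
    ).to_csv(paths["meta"], index=False)
    pd.DataFrame({"depth_cm": model.depths, "age_calBP": model.ages}).to_csv(
        paths["agedepth"], index=False
    )
    samples.groups.rename_axis("taxon").reset_index().to_csv(paths["groups"], index=False)
    return paths


def write_results(out_dir, ensemble=None, evenness=None, windows=None) -> dict:
    """Write analysis results as flat CSV tables.

    One file per result type, deterministic column order, full float
    precision (``repr`` round-trip). Returns the mapping of result name to
    path. Any of the result objects may be ``None`` and is then skipped;
    empty results yield header-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if ensemble is not None:
        df = pd.DataFrame({"bin_age_calBP": ensemble.bin_ages})
        df["median_ET"] = ensemble.median_series
        for level in sorted(ensemble.percentile_series):
            df[f"q{level:g}_ET"] = ensemble.percentile_series[level]
        df["minimax_ET"] = ensemble.minimax_series
        paths["rarefaction"] = out / "rarefaction.csv"
        df.to_csv(paths["rarefaction"], index=False)

        surf = pd.DataFrame(
            ensemble.E,
            index=pd.Index(ensemble.bin_ages, name="bin_age_calBP"),
            columns=[f"n{v}" for v in ensemble.n_prime_values],
        )
        paths["rarefaction_surface"] = out / "rarefaction_surface.csv"
        surf.reset_index().to_csv(paths["rarefaction_surface"], index=False)

    if evenness is not None:
        paths["evenness"] = out / "evenness.csv"
        pd.DataFrame(
            {"bin_age_calBP": evenness.bin_ages, "delta1": evenness.delta1}
        ).to_csv(paths["evenness"], index=False)

    if windows is not None:
        paths["windows"] = out / "windows.csv"
        rows = []
        for i in range(len(windows.window_starts)):
            vals = windows.values[i]
            rows.append(
                {
                    "window_start_calBP": windows.window_starts[i],
                    "window_end_calBP": windows.window_starts[i] + windows.width,
                    "n_bins": len(vals),
                    "median": float(np.median(vals)),
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                    "letters": windows.letters[i],
                    "kw_H": windows.H,
                    "kw_p": windows.p_value,
                }
            )
        cols = [
            "window_start_calBP", "window_end_calBP", "n_bins",
            "median", "min", "max", "letters", "kw_H", "kw_p",
        ]
        pd.DataFrame(rows, columns=cols).to_csv(paths["windows"], index=False)

        if windows.posthoc_p is not None:
            paths["posthoc"] = out / "posthoc_p.csv"
            lab = [f"w{int(s)}" for s in windows.window_starts]
            pd.DataFrame(windows.posthoc_p, index=pd.Index(lab, name="window"), columns=lab) \
                .reset_index().to_csv(paths["posthoc"], index=False)

    return paths


def write_resampled(record, path) -> Path:
    """Write a resampled record as one flat table (bins x diagnostics+taxa)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "bin_age_calBP": record.bin_ages,
            "bin_start_calBP": record.bin_edges,
            "sed_rate_cm_yr": record.sed_rate,
            "coverage": record.coverage,
        }
    )
    for t in record.influx.columns:
        df[f"influx__{t}"] = record.influx[t].to_numpy()
    df.attrs["w"] = record.w
    header = f"# w_yr={record.w}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_resampled(path):
    """Read a table written by :func:`write_resampled`.

    Returns (influx DataFrame indexed by bin age, metadata dict).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# w_yr="):
            raise RecordValidationError(f"{path} is not a resampled-record table")
        w = int(float(first.strip().split("=", 1)[1]))
        df = pd.read_csv(fh)
    taxa_cols = [c for c in df.columns if c.startswith("influx__")]
    influx = df[taxa_cols].copy()
    influx.columns = [c[len("influx__"):] for c in taxa_cols]
    influx.index = pd.Index(df["bin_age_calBP"], name="bin_age_calBP")
    meta = {
        "w": w,
        "bin_ages": df["bin_age_calBP"].to_numpy(),
        "bin_edges": df["bin_start_calBP"].to_numpy(),
        "sed_rate": df["sed_rate_cm_yr"].to_numpy(),
        "coverage": df["coverage"].to_numpy(),
    }
    return influx, meta
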