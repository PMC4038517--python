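"""Screen-level composition statistics for sgRNA activity.

Works on a screen table: one row per sgRNA with its 20-nt protospacer,
5' dinucleotide class, background-corrected indel frequency ("cut rate"),
and optionally the PAM and a survival fraction.  The statistics mirror a
large-scale mutagenesis screen readout: the fraction of active guides and
mean activity, activity stratified by G/C content, per-position nucleotide
bias as log2 fold change of mean cut rate over the global mean, and 5'
dinucleotide group comparisons (e.g. how much worse 5'AG guides do than
5'GG ones).

The screen table is a pandas DataFrame with columns ``target``,
``protospacer``, ``dinuc``, ``indel_freq`` and optionally ``pam`` and
``survival``; :func:`crispamp.io.load_screen_table` maps arbitrary column
layouts onto this schema.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "screen_summary",
    "position_bias",
    "gc_strata",
    "dinuc_groups",
]

_BASES = ("A", "C", "G", "T")
#: Positions reported in the bias matrix: protospacer 3-20 plus the PAM N
#: at 21.  Positions 1-2 are promoter-constrained and excluded.
BIAS_POSITIONS = tuple(range(3, 22))


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"protospacer", "indel_freq"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"screen table lacks columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("empty screen table")
    bad = records["protospacer"].str.len() != 20
    if bad.any():
        raise ValueError("all protospacers must be 20 nt")
    return records


def screen_summary(records: pd.DataFrame, active_threshold: float = 0.0) -> dict:
    """Overall screen readout: target count, active fraction, mean activity.

    A guide is active when its corrected indel frequency exceeds
    ``active_threshold`` (default: any non-zero activity).  ``mean_freq``
    averages over all records; ``mean_freq_active`` over active ones only.
    """
    records = _check_records(records)
    freq = records["indel_freq"].to_numpy(float)
    active = freq > active_threshold
    return {
        "n_targets": int(len(records)),
        "active_fraction": float(active.mean()),
        "mean_freq": float(freq.mean()),
        "mean_freq_active": float(freq[active].mean()) if active.any() else float("nan"),
    }


def _base_at(records: pd.DataFrame, pos: int) -> pd.Series:
    """Base at 1-based position ``pos``: protospacer 1-20, PAM N at 21."""
    if pos <= 20:
        return records["protospacer"].str[pos - 1]
    if "pam" in records.columns:
        return records["pam"].str[pos - 21]
    return pd.Series(np.nan, index=records.index, dtype=object)


def position_bias(
    records: pd.DataFrame, positions: tuple[int, ...] = BIAS_POSITIONS
) -> dict[str, pd.DataFrame]:
    """Per-position nucleotide bias of cut rates.

    For every (position, base) cell: the number of guides, their mean cut
    rate, and log2(mean over guides with that base / mean over all guides).
    Cells with no guides, or where either mean is zero, are NaN rather than
    -inf.  Returns ``{"count", "mean", "log2fc"}`` DataFrames indexed by
    position with one column per base.
    """
    records = _check_records(records)
    if len(records) < 2:
        raise ValueError("position bias requires at least two records")
    freq = records["indel_freq"].to_numpy(float)
    overall = freq.mean()
    if overall == 0:
        warnings.warn("overall mean cut rate is zero; bias matrix is all-NA")
    count = pd.DataFrame(0, index=list(positions), columns=list(_BASES))
    mean = pd.DataFrame(np.nan, index=list(positions), columns=list(_BASES))
    fc = pd.DataFrame(np.nan, index=list(positions), columns=list(_BASES))
    for pos in positions:
        bases = _base_at(records, pos)
        for b in _BASES:
            mask = (bases == b).to_numpy()
            n = int(mask.sum())
            count.loc[pos, b] = n
            if n == 0:
                continue
            mb = freq[mask].mean()
            mean.loc[pos, b] = mb
            if overall > 0 and mb > 0:
                fc.loc[pos, b] = np.log2(mb / overall)
    return {"count": count, "mean": mean, "log2fc": fc, "overall_mean": overall}


def gc_strata(
    records: pd.DataFrame, bin_edges: list[float] | None = None
) -> pd.DataFrame:
    """Mean cut rate stratified by protospacer G/C content.

    By default guides are keyed by their exact G/C count out of 20
    (multiples of 5%); ``bin_edges`` switches to interval bins over the
    G/C fraction (right-open, last bin closed).  Empty strata are NaN.
    """
    records = _check_records(records)
    gc = (
        records["protospacer"].str.count("G")
        + records["protospacer"].str.count("C")
    )
    freq = records["indel_freq"].astype(float)
    if bin_edges is None:
        grouped = freq.groupby(gc.rename("gc_count"))
        out = pd.DataFrame(
            {"n": grouped.size(), "mean_freq": grouped.mean()}
        ).reindex(range(21))
        out["n"] = out["n"].fillna(0).astype(int)
        out.index.name = "gc_count"
    else:
        if bin_edges[0] > 0 or bin_edges[-1] < 1:
            raise ValueError("bin edges must cover [0, 1]")
        cats = pd.cut(gc / 20, bin_edges, include_lowest=True)
        grouped = freq.groupby(cats, observed=False)
        out = pd.DataFrame({"n": grouped.size(), "mean_freq": grouped.mean()})
        out.index.name = "gc_bin"
    out.attrs["overall_mean"] = float(freq.mean())
    return out


def dinuc_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Activity by 5' dinucleotide class, with fold change versus 5'GG.

    ``fold_vs_GG`` is mean(GG) / mean(group): a value of 5 for AG means AG
    guides average five-fold lower activity than GG guides.  Groups with a
    zero mean (or an absent GG group) yield NaN folds.
    """
    records = _check_records(records)
    if "dinuc" in records.columns:
        dinuc = records["dinuc"]
    else:
        first2 = records["protospacer"].str[:2]
        dinuc = first2.where(first2.isin(["GG", "GA", "AG"]), "other")
    freq = records["indel_freq"].astype(float)
    grouped = freq.groupby(dinuc.rename("dinuc"))
    out = pd.DataFrame({"n": grouped.size(), "mean_freq": grouped.mean()})
    out = out.reindex(["GG", "GA", "AG"]).dropna(how="all")
    out["n"] = out["n"].fillna(0).astype(int)
    mean_gg = out["mean_freq"].get("GG", np.nan)
    out["fold_vs_GG"] = np.where(
        (out["mean_freq"] > 0) & np.isfinite(mean_gg),
        mean_gg / out["mean_freq"],
        np.nan,
    )
    return out
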