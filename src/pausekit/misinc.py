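"""Per-position transcription-error statistics for two conditions.

Consensus reads (one per RNA molecule, UMI-collapsed upstream) are
tabulated into per-position base counts against the reference.  For each
position the error fraction is the non-reference count over coverage; the
two conditions are contrasted by the relative percent error
100 * (p_plus - p_minus) / p_minus and by a two-sided Fisher exact test on
the 2x2 (error, correct) x (plus, minus) table.  Positions with p < 0.05
and increased error populate the upper-right region of a volcano plot.
The mismatch burden summarises, per condition, the fraction of reads with
0, 1, 2, 3 or more than 3 mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BaseCountMatrix",
    "per_position_error",
    "relative_percent_error",
    "position_fisher",
    "mismatch_burden",
    "counts_from_reads",
    "per_read_mismatches",
]

ALPHABET = ("A", "C", "G", "T")
UNDEFINED = float("nan")


@dataclass
class BaseCountMatrix:
    """Per-position base counts for one condition.

    ``counts`` is indexed by 1-based reference position with columns
    A, C, G, T; ``reference`` is the reference sequence (U read as T);
    ``condition`` a free-text label.
    """

    counts: pd.DataFrame
    reference: str
    condition: str = ""

    def __post_init__(self) -> None:
        self.reference = self.reference.upper().replace("U", "T")
        if set(self.reference) - set(ALPHABET):
            raise ValueError("reference contains non-ACGT/U symbols")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if len(self.reference) != len(self.counts):
            raise ValueError("reference length != number of count rows")
        missing = [b for b in ALPHABET if b not in self.counts.columns]
        if missing:
            raise ValueError(f"count matrix missing base column(s) {missing}")

    def ref_base(self, position: int) -> str:
        return self.reference[position - 1]


def counts_from_reads(reads, reference: str,
                      condition: str = "") -> BaseCountMatrix:
    """Tabulate gapless, reference-length consensus reads into base counts.

    ``reads`` is an iterable of sequences (or Biopython SeqRecords); each
    must have the same length as ``reference``.
    """
    ref = reference.upper().replace("U", "T")
    counts = np.zeros((len(ref), 4), dtype=np.int64)
    col = {b: i for i, b in enumerate(ALPHABET)}
    n = 0
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper().replace("U", "T")
        if len(seq) != len(ref):
            raise ValueError(
                f"read length {len(seq)} != reference length {len(ref)}; "
                "reads must be gapless and aligned")
        for i, b in enumerate(seq):
            if b in col:
                counts[i, col[b]] += 1
        n += 1
    if n == 0:
        raise ValueError("no reads supplied")
    return BaseCountMatrix(
        counts=pd.DataFrame(counts, index=np.arange(1, len(ref) + 1),
                            columns=list(ALPHABET)),
        reference=ref, condition=condition)


def per_read_mismatches(reads, reference: str) -> np.ndarray:
    """Number of non-reference bases per read (gapless, equal length)."""
    ref = np.frombuffer(
        reference.upper().replace("U", "T").encode(), dtype="S1")
    out = []
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper().replace("U", "T")
        arr = np.frombuffer(seq.encode(), dtype="S1")
        if arr.size != ref.size:
            raise ValueError("read length != reference length")
        out.append(int((arr != ref).sum()))
    return np.asarray(out, dtype=np.int64)


def per_position_error(matrix: BaseCountMatrix) -> pd.DataFrame:
    """Error fraction and substitution composition at each position.

    The error fraction is the non-reference count over total coverage;
    the composition columns (frac_A ... frac_T) normalise counts over the
    non-reference bases only (the input to a substitution sequence logo).
    Zero-coverage positions are skipped with a warning.
    """
    rows = []
    for pos in matrix.counts.index:
        counts = matrix.counts.loc[pos]
        total = int(counts.sum())
        if total == 0:
            warnings.warn(f"position {pos} has zero coverage; skipped")
            continue
        ref = matrix.ref_base(int(pos))
        err = int(total - counts[ref])
        row = {"position": int(pos), "ref": ref, "coverage": total,
               "error_fraction": err / total}
        for b in ALPHABET:
            row[f"frac_{b}"] = (counts[b] / err if (err > 0 and b != ref)
                                else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


def relative_percent_error(err_plus, err_minus,
                           mode: str = "difference"):
    """Per-position contrast of error fractions, in percent.

    ``difference`` (default): 100 * (p_plus - p_minus) / p_minus.
    ``ratio``: 100 * p_plus / p_minus.  Positions with p_minus == 0 are
    undefined and returned as NaN, never silent infinity.
    """
    p = np.asarray(err_plus, dtype=float)
    m = np.asarray(err_minus, dtype=float)
    if ((p < 0) | (p > 1)).any() or ((m < 0) | (m > 1)).any():
        raise ValueError("error fractions must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "difference":
            out = 100.0 * (p - m) / m
        elif mode == "ratio":
            out = 100.0 * p / m
        else:
            raise ValueError(f"unknown mode {mode!r}")
    out = np.where(m == 0, UNDEFINED, out)
    return float(out) if out.ndim == 0 else out


def position_fisher(matrix_plus: BaseCountMatrix,
                    matrix_minus: BaseCountMatrix,
                    alpha: float = 0.05,
                    mode: str = "difference") -> pd.DataFrame:
    """Volcano-style error-call table for two matched count matrices.

    Per position: error fractions in each condition, the relative percent
    error, a two-sided Fisher exact p-value on the (error, correct) x
    (plus, minus) table, the significance call (p < alpha AND increased
    error in the plus condition), and the dominant misincorporated base
    (pooled across conditions).
    """
    if matrix_plus.reference != matrix_minus.reference:
        raise ValueError("count matrices have different references")
    rows = []
    for pos in matrix_plus.counts.index:
        ref = matrix_plus.ref_base(int(pos))
        cp = matrix_plus.counts.loc[pos]
        cm = matrix_minus.counts.loc[pos]
        tp, tm = int(cp.sum()), int(cm.sum())
        if tp == 0 or tm == 0:
            warnings.warn(f"position {pos} has zero coverage; skipped")
            continue
        ep, em = int(tp - cp[ref]), int(tm - cm[ref])
        table = [[ep, tp - ep], [em, tm - em]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rel = relative_percent_error(ep / tp, em / tm, mode=mode)
        increased = (ep / tp > em / tm) if mode == "ratio" else \
            (np.isfinite(rel) and rel > 0)
        pooled = cp.drop(ref) + cm.drop(ref)
        dominant = pooled.idxmax() if pooled.sum() > 0 else ""
        rows.append({
            "position": int(pos), "ref": ref,
            "err_minus": em / tm, "err_plus": ep / tp,
            "rel_percent_error": rel, "p_value": float(p),
            "significant": bool(p < alpha and increased),
            "dominant_misincorporated_base": dominant,
        })
    return pd.DataFrame(rows).set_index("position")


def mismatch_burden(per_read_counts) -> dict:
    """Fractions of reads with 0, 1, 2, 3 and >3 mismatches.

    Returns a dict with keys "0", "1", "2", "3", ">3" (summing to 1) and
    "ge1", the fraction of reads carrying at least one mismatch.
    """
    c = np.asarray(per_read_counts, dtype=np.int64)
    if c.size == 0:
        raise ValueError("no reads")
    n = c.size
    out = {str(k): float((c == k).sum() / n) for k in (0, 1, 2, 3)}
    out[">3"] = float((c > 3).sum() / n)
    out["ge1"] = float((c >= 1).sum() / n)
    return out
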