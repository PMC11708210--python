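"""Sliding-window match complexity and its random-sequence null model.

The match complexity of a window is

    Cm = (mo - 1) / (me - 1)

where ``mo`` is the observed number of maximal-match factors intersecting
the window and ``me`` its expectation for i.i.d. random sequence of the
same length and base composition as the genome. The subtraction of 1 puts
perfect repeats (a single factor spanning the window, ``mo = 1``) at
``Cm = 0`` and random sequence at an expectation of 1. Windows whose Cm
is indistinguishable from the random-sequence null have no close homolog
elsewhere in the genome: they are *unique*.

``me`` and the null distribution of Cm are calibrated by Monte Carlo:
random sequences of the genome's length and composition are indexed and
windowed exactly as the genome is, and the resulting factor counts give
both the expectation and the empirical null quantiles used to classify
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqindex import (
    Factorization,
    MatchIndex,
    SequenceRecord,
    build_index,
    factorize,
    matching_statistics,
    random_residues,
)

__all__ = [
    "WindowConfig",
    "NullModel",
    "CalibrationError",
    "calibrate_null",
    "window_starts",
    "window_complexity",
    "profile_genome",
    "classify_unique",
    "write_profile",
    "read_profile",
]

DEFAULT_ALPHA = 0.05
DEFAULT_REPLICATES = 20
MAX_N_FRACTION = 0.5  # windows with more N than this get a missing Cm


class CalibrationError(ValueError):
    """Raised when the null model cannot be calibrated (me <= 1)."""


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: window length and step, both in bp.

    The stride defaults to a tenth of the window (e.g. 1 kb steps for
    10 kb windows) so that region boundaries are resolved at a tenth of
    the window length.
    """

    window_length: int
    step: int | None = None

    def __post_init__(self) -> None:
        if self.step is None:
            object.__setattr__(self, "step", max(1, self.window_length // 10))
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not (1 <= self.step <= self.window_length):
            raise ValueError("step must satisfy 1 <= step <= window_length")


def window_starts(length: int, cfg: WindowConfig) -> np.ndarray:
    """Start positions of all windows on a chromosome of ``length`` bp.

    Windows advance by ``cfg.step``; the last window is flush with the
    chromosome end. Chromosomes shorter than the window yield no windows.
    """
    w = cfg.window_length
    if length < w:
        return np.zeros(0, dtype=np.int64)
    starts = np.arange(0, length - w + 1, cfg.step, dtype=np.int64)
    if starts[-1] != length - w:
        starts = np.append(starts, length - w)
    return starts


@dataclass
class NullModel:
    """Expectation ``me`` and empirical null distribution of window Cm.

    Calibrated on i.i.d. random sequences matched to the genome in total
    length and global base composition, windowed with the same geometry
    as the genome analysis.
    """

    me: float
    null_cm: np.ndarray  # sorted
    window_length: int
    step: int
    total_length: int
    composition: np.ndarray
    replicates: int
    seed: int | None = None

    def quantile(self, p) -> float:
        return float(np.quantile(self.null_cm, p))

    def threshold(self, alpha: float) -> float:
        """The lower-tail Cm cutoff below which a window is repeat-like."""
        return self.quantile(alpha)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"me\t{self.me!r}\n")
            fh.write(f"window_length\t{self.window_length}\n")
            fh.write(f"step\t{self.step}\n")
            fh.write(f"total_length\t{self.total_length}\n")
            fh.write(
                "composition\t" + ",".join(repr(float(x)) for x in self.composition) + "\n"
            )
            fh.write(f"replicates\t{self.replicates}\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write("null_cm\t" + ",".join(repr(float(x)) for x in self.null_cm) + "\n")

    @classmethod
    def load(cls, path) -> "NullModel":
        kv: dict = {}
        with open(path) as fh:
            for line in fh:
                key, _, val = line.rstrip("\n").partition("\t")
                kv[key] = val
        return cls(
            me=float(kv["me"]),
            null_cm=np.array([float(x) for x in kv["null_cm"].split(",")]),
            window_length=int(kv["window_length"]),
            step=int(kv["step"]),
            total_length=int(kv["total_length"]),
            composition=np.array([float(x) for x in kv["composition"].split(",")]),
            replicates=int(kv["replicates"]),
            seed=None if kv.get("seed") == "None" else int(kv["seed"]),
        )


def _window_counts(index: MatchIndex, cfg: WindowConfig) -> np.ndarray:
    """Factor counts mo for every window of every chromosome of ``index``."""
    ms = matching_statistics(index)
    counts = []
    for rec in index.records:
        starts = window_starts(rec.length, cfg)
        if len(starts) == 0:
            continue
        fact = factorize(ms[rec.id])
        counts.append(fact.factor_counts(starts, starts + cfg.window_length))
    if not counts:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(counts)


def calibrate_null(
    total_length: int,
    composition,
    cfg: WindowConfig,
    replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
) -> NullModel:
    """Monte Carlo calibration of ``me`` and the null Cm distribution.

    Each replicate draws an i.i.d. sequence of ``total_length`` bp with
    the given base composition, indexes it (both strands) and collects
    the factor count of every window. ``me`` is the mean observed count;
    the null Cm sample is ``(mo - 1)/(me - 1)`` over all null windows.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if total_length < cfg.window_length:
        raise ValueError("total_length shorter than the window")
    rng = np.random.default_rng(seed)
    composition = np.asarray(composition, dtype=float)
    all_counts = []
    for _ in range(replicates):
        seq = random_residues(total_length, composition, rng)
        idx = build_index([SequenceRecord("null", seq)])
        all_counts.append(_window_counts(idx, cfg))
    mo = np.concatenate(all_counts).astype(float)
    me = float(mo.mean())
    if me <= 1.0:
        raise CalibrationError(
            f"null expectation me={me:.3f} <= 1; use a larger window or longer sequence"
        )
    null_cm = np.sort((mo - 1.0) / (me - 1.0))
    return NullModel(
        me=me,
        null_cm=null_cm,
        window_length=cfg.window_length,
        step=cfg.step,
        total_length=total_length,
        composition=composition,
        replicates=replicates,
        seed=seed,
    )


def window_complexity(
    factorizations: dict,
    chrom_lengths: dict,
    cfg: WindowConfig,
    null: NullModel,
    n_masks: dict | None = None,
) -> pd.DataFrame:
    """Per-window rows ``(chromosome, start, end, mo, Cm)``.

    ``factorizations`` maps each chromosome to its whole-chromosome
    greedy :class:`~urscan.seqindex.Factorization` (computed once from
    position 0; every window's ``mo`` counts the precomputed factors it
    intersects). Windows with more than half their residues ``N`` get a
    missing (NaN) Cm: assembly gaps are not repeats.
    """
    if null.window_length != cfg.window_length:
        raise ValueError("null model calibrated with a different window length")
    rows = []
    for chrom, L in chrom_lengths.items():
        starts = window_starts(L, cfg)
        if len(starts) == 0:
            continue
        fact = factorizations[chrom]
        mo = fact.factor_counts(starts, starts + cfg.window_length)
        cm = (mo - 1.0) / (null.me - 1.0)
        if n_masks is not None and chrom in n_masks:
            ncum = np.concatenate([[0], np.cumsum(n_masks[chrom].astype(np.int64))])
            nfrac = (ncum[starts + cfg.window_length] - ncum[starts]) / cfg.window_length
            cm = np.where(nfrac > MAX_N_FRACTION, np.nan, cm)
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start": starts,
                    "end": starts + cfg.window_length,
                    "mo": mo,
                    "Cm": cm,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chromosome", "start", "end", "mo", "Cm"])
    return pd.concat(rows, ignore_index=True)


def profile_genome(index: MatchIndex, cfg: WindowConfig, null: NullModel) -> pd.DataFrame:
    """Convenience: matching statistics, factorization and Cm in one call."""
    ms = matching_statistics(index)
    factorizations = {rec.id: factorize(ms[rec.id]) for rec in index.records}
    n_masks = {
        rec.id: np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8) == ord("N")
        for rec in index.records
    }
    return window_complexity(
        factorizations, index.chromosome_lengths, cfg, null, n_masks=n_masks
    )


def classify_unique(
    profile: pd.DataFrame, null: NullModel, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Flag windows indistinguishable from random (one-sided lower test).

    A window is unique iff its Cm is at or above the alpha-quantile of
    the null Cm distribution; low Cm means repeat-like. Ties at the
    threshold are inclusive. Windows with missing Cm are never unique.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError("alpha must be in (0, 0.5]")
    thr = null.threshold(alpha)
    out = profile.copy()
    out["unique"] = (out["Cm"] >= thr) & out["Cm"].notna()
    return out


def write_profile(profile: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}={v}\n")
        profile.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_profile(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
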