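"""B-cell receptor repertoire surveillance.

Clonotypes are groups of heavy-chain rearrangements sharing the same V gene,
the same J gene, and >= 80% CDR3 amino-acid identity (single-linkage over
Hamming identity on equal-length CDR3s).  On top of the clonal partition the
module quantifies somatic hypermutation (percent divergence of the aligned V
region from germline), isotype and V-family spectra, CDR3 length
distributions, V-J pairing matrices, canonical-clone (VH1-72 / W33L)
tracking, clone-size statistics, and Kullback-Leibler sequence logos in
which depleted residues plot below the axis.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import KNOWN_ISOTYPES, GermlineSegment, Rearrangement, parse_isotype
from .stats_core import TestReport, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "Clone",
    "CloneSet",
    "LogoMatrix",
    "assign_clonotypes",
    "vh_mutation_stats",
    "mutated_clonotype_frequency",
    "isotype_frequencies",
    "vfamily_and_vj_matrix",
    "cdr3_length_distribution",
    "vh1_72_analysis",
    "clone_size_stats",
    "kl_logo",
    "AMINO_ACIDS",
]

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")
_GAP_CHARS = {"-", "."}


@dataclass
class Clone:
    clone_id: int
    member_indices: list[int]
    v_call: str
    j_call: str
    ancestor_cdr3: str
    size: int
    mean_vh_mutation_freq: float
    isotype_counts: dict = field(default_factory=dict)


@dataclass
class CloneSet:
    """Partition of rearrangements into clonotypes.

    ``assignments[i]`` is the clone_id of record *i*; clone sizes sum to the
    number of assigned records.
    """

    clones: list[Clone]
    assignments: np.ndarray
    n_records: int

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clones], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": [c.clone_id for c in self.clones],
                "v_call": [c.v_call for c in self.clones],
                "j_call": [c.j_call for c in self.clones],
                "ancestor_cdr3": [c.ancestor_cdr3 for c in self.clones],
                "size": [c.size for c in self.clones],
                "mean_vh_mutation_freq": [c.mean_vh_mutation_freq for c in self.clones],
            }
        )


def _hamming_identity_components(cdr3s: list[str], threshold: float, linkage: str) -> np.ndarray:
    """Cluster equal-length CDR3s by Hamming identity >= threshold."""
    n = len(cdr3s)
    if n == 1:
        return np.zeros(1, dtype=int)
    L = len(cdr3s[0])
    arr = np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(n, L)
    # pairwise identity in blocks to bound memory
    rows, cols = [], []
    block = max(1, int(4e6 // (n * L)) or 1)
    for start in range(0, n, block):
        stop = min(start + block, n)
        eq = (arr[start:stop, None, :] == arr[None, :, :]).sum(axis=2)
        ident = eq / L
        r, c = np.nonzero(ident >= threshold - 1e-12)
        rows.append(r + start)
        cols.append(c)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    if linkage == "single":
        adj = coo_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        return labels
    if linkage == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage as hlink
        from scipy.spatial.distance import squareform

        eq = (arr[:, None, :] == arr[None, :, :]).sum(axis=2) / L
        dist = 1.0 - eq
        np.fill_diagonal(dist, 0.0)
        Z = hlink(squareform(dist, checks=False), method="complete")
        return fcluster(Z, t=1.0 - threshold + 1e-9, criterion="distance") - 1
    raise ValueError(f"unknown linkage {linkage!r}")


def assign_clonotypes(
    records: list[Rearrangement],
    identity_threshold: float = 0.80,
    linkage: str = "single",
) -> CloneSet:
    """Partition rearrangements into clonotypes.

    Records first split by (v_call, j_call, CDR3 length); within each split,
    records are clustered with an edge whenever CDR3 Hamming identity is
    >= ``identity_threshold`` (inclusive).  Single-linkage closure by
    default, so the partition is invariant to record order.
    """
    n = len(records)
    assignments = np.full(n, -1, dtype=int)
    clones: list[Clone] = []
    partitions: dict[tuple, list[int]] = defaultdict(list)
    for i, r in enumerate(records):
        partitions[(r.v_call, r.j_call, len(r.cdr3_aa))].append(i)

    next_id = 0
    for key in sorted(partitions):
        idx = partitions[key]
        cdr3s = [records[i].cdr3_aa for i in idx]
        labels = _hamming_identity_components(cdr3s, identity_threshold, linkage)
        for lab in range(labels.max() + 1):
            members = [idx[j] for j in np.flatnonzero(labels == lab)]
            member_cdr3s = [records[i].cdr3_aa for i in members]
            ancestor = min(Counter(member_cdr3s).most_common(),
                           key=lambda kv: (-kv[1], kv[0]))[0]
            # mutation burden: each distinct variant sequence counted once
            variants = {}
            for i in members:
                rec = records[i]
                if rec.v_seq_aligned and rec.germline_v_aligned:
                    variants.setdefault(rec.v_seq_aligned, i)
            if variants:
                freqs = [vh_mutation_stats(records[i])[1] for i in variants.values()]
                mean_freq = float(np.mean(freqs))
            else:
                mean_freq = float("nan")
            iso_counts = Counter(parse_isotype(records[i].c_call) for i in members)
            clones.append(
                Clone(
                    clone_id=next_id,
                    member_indices=members,
                    v_call=key[0],
                    j_call=key[1],
                    ancestor_cdr3=ancestor,
                    size=len(members),
                    mean_vh_mutation_freq=mean_freq,
                    isotype_counts=dict(iso_counts),
                )
            )
            assignments[members] = next_id
            next_id += 1
    return CloneSet(clones=clones, assignments=assignments, n_records=n)


def vh_mutation_stats(rearrangement: Rearrangement) -> tuple[int, float]:
    """Mutation count and percent frequency of an aligned V region.

    Counts positions where both the sequence and its germline are non-gap
    and differ; the frequency denominator is the non-gap aligned length.
    """
    seq = rearrangement.v_seq_aligned
    germ = rearrangement.germline_v_aligned
    if len(seq) != len(germ):
        raise ValueError(
            f"aligned V ({len(seq)}) and germline ({len(germ)}) lengths differ "
            f"for cell {rearrangement.cell_id}"
        )
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(germ.encode(), dtype=np.uint8)
    gap = np.frombuffer("-.".encode(), dtype=np.uint8)
    valid = ~(np.isin(a, gap) | np.isin(b, gap))
    denom = int(valid.sum())
    count = int((a[valid] != b[valid]).sum())
    freq = 100.0 * count / denom if denom else float("nan")
    return count, freq


def mutated_clonotype_frequency(
    clones: CloneSet,
    freq_threshold: float = 2.0,
    min_clone_size: int = 10,
    denominator: str = "sequences",
) -> float | None:
    """Frequency of highly mutated expanded clonotypes in one sample.

    A clone qualifies when its size is strictly greater than
    ``min_clone_size`` and its mean VH mutation frequency strictly exceeds
    ``freq_threshold`` percent.  The denominator convention:

    * ``"sequences"`` (default): qualifying clones' member sequences over all
      sequences in the sample — the per-sequence frequency a repertoire
      pipeline reports per mouse;
    * ``"qualifying_clones"``: mutated clones over clones larger than the
      size cutoff;
    * ``"all_clones"``: mutated qualifying clones over all clones.

    Returns ``None`` (missing, not 0) when the denominator is empty.
    """
    big = [c for c in clones.clones if c.size > min_clone_size]
    mutated = [c for c in big
               if np.isfinite(c.mean_vh_mutation_freq)
               and c.mean_vh_mutation_freq > freq_threshold]
    if denominator == "sequences":
        if clones.n_records == 0:
            return None
        return sum(c.size for c in mutated) / clones.n_records
    if denominator == "qualifying_clones":
        if not big:
            return None
        return len(mutated) / len(big)
    if denominator == "all_clones":
        if not clones.clones:
            return None
        return len(mutated) / len(clones.clones)
    raise ValueError(f"unknown denominator {denominator!r}")


def isotype_frequencies(
    records: list[Rearrangement], by_sample: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample isotype fractions over known isotypes (each row sums to 1).

    Unknown isotypes are excluded from the fractions and reported separately
    as counts.
    """
    if not records:
        raise ValueError("no rearrangements")
    samples = [r.sample_id or "all" for r in records] if by_sample else ["all"] * len(records)
    df = pd.DataFrame({"sample_id": samples,
                       "isotype": [parse_isotype(r.c_call) for r in records]})
    unknown = df[df["isotype"] == "unknown"].groupby("sample_id").size()
    unknown = unknown.reindex(sorted(df["sample_id"].unique()), fill_value=0)
    known = df[df["isotype"] != "unknown"]
    counts = (
        known.groupby(["sample_id", "isotype"], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=KNOWN_ISOTYPES, fill_value=0)
    freqs = counts.div(counts.sum(axis=1), axis=0).fillna(0.0)
    return freqs, unknown


def vfamily_and_vj_matrix(
    records: list[Rearrangement], clones: CloneSet | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """V-family usage frequencies and the V x J pairing count matrix.

    Family is the prefix before the first hyphen of the V call (VH1 from
    VH1-72).  With a CloneSet, each clone is counted once (clone-collapsed
    mode for Circos-style export); otherwise each record counts.
    """
    if clones is not None:
        vs = [c.v_call for c in clones.clones]
        js = [c.j_call for c in clones.clones]
    else:
        vs = [r.v_call for r in records]
        js = [r.j_call for r in records]
    if not vs:
        raise ValueError("no records")
    fams = [v.split("-")[0] for v in vs]
    fam_freq = pd.Series(Counter(fams)).sort_index()
    fam_freq = fam_freq / fam_freq.sum()
    vj = pd.crosstab(pd.Series(vs, name="v"), pd.Series(js, name="j"))
    return fam_freq, vj


def vj_long_format(vj: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Circos-compatible long format (v, j, count), optionally top-k pairs."""
    long = vj.stack().reset_index()
    long.columns = ["v", "j", "count"]
    long = long[long["count"] > 0].sort_values("count", ascending=False)
    if top_k is not None:
        long = long.head(top_k)
    return long.reset_index(drop=True)


def cdr3_length_distribution(records: list[Rearrangement]) -> dict:
    """CDR3 amino-acid length distribution.

    Returns frequencies per integer length (summing to 1), the trapezoidal
    area under the frequency polygon (AUC), and the modal length.
    """
    if not records:
        raise ValueError("no rearrangements")
    lengths = pd.Series([len(r.cdr3_aa) for r in records])
    counts = lengths.value_counts().sort_index()
    freqs = counts / counts.sum()
    x = freqs.index.to_numpy(dtype=float)
    y = freqs.to_numpy(dtype=float)
    auc = float(np.trapezoid(y, x)) if len(x) > 1 else 0.0
    mode = int(counts.index[counts.to_numpy().argmax()])
    return {"frequencies": freqs, "auc": auc, "modal_length": mode}


def _translate_window(
    rec: Rearrangement, germ: GermlineSegment, window_len: int
) -> str | None:
    """Extract and translate the CDR1 window of an aligned (gap-free) V."""
    start_aa = germ.cdr1_aa_start
    if start_aa is None:
        return None
    nt_start = (start_aa - 1) * 3
    nt_stop = nt_start + window_len * 3
    seq = rec.v_seq_aligned
    if len(seq) < nt_stop or any(ch in _GAP_CHARS for ch in seq[nt_start:nt_stop]):
        return None
    return str(Seq(seq[nt_start:nt_stop]).translate())


def vh1_72_analysis(
    records: list[Rearrangement],
    germlines: dict[str, GermlineSegment],
    canonical_v: str = "VH1-72",
    cdr1_window_len: int = 8,
    w33l_pos: int = 8,
) -> dict:
    """Canonical-clone usage and W33L tracking.

    Per sample: the fraction of records using ``canonical_v``; among those,
    counts of residue L vs W (vs other) at 1-based CDR1 window position
    ``w33l_pos`` (position 8 of the window corresponds to VH amino acid 33).
    Records whose window extends past the alignment are flagged and excluded
    from the W33L counts.  The translated windows are returned per sample
    for logo construction.
    """
    germ = germlines.get(canonical_v)
    if germ is None:
        raise KeyError(f"germline segment {canonical_v!r} not provided")
    samples = sorted({r.sample_id or "all" for r in records})
    usage = {}
    w33l_counts = {}
    windows: dict[str, list[str]] = {s: [] for s in samples}
    n_flagged = 0
    for s in samples:
        sub = [r for r in records if (r.sample_id or "all") == s]
        canon = [r for r in sub if r.v_call == canonical_v]
        usage[s] = len(canon) / len(sub) if sub else float("nan")
        counts = {"W": 0, "L": 0, "other": 0}
        for r in canon:
            win = _translate_window(r, germ, cdr1_window_len)
            if win is None:
                n_flagged += 1
                continue
            windows[s].append(win)
            aa = win[w33l_pos - 1]
            counts[aa if aa in ("W", "L") else "other"] += 1
        w33l_counts[s] = counts
    if n_flagged:
        logger.warning("vh1_72_analysis: %d records lacked a complete CDR1 window", n_flagged)
    return {
        "usage": pd.Series(usage, name="vh1_72_usage"),
        "w33l_counts": pd.DataFrame(w33l_counts).T[["W", "L", "other"]],
        "windows": windows,
        "n_flagged": n_flagged,
    }


def clone_size_stats(
    clonesets_by_group: dict[str, CloneSet], min_size: int = 2
) -> tuple[pd.DataFrame, TestReport | None]:
    """log10 clone sizes per group with a Mann-Whitney group comparison.

    By default restricted to clones with at least ``min_size`` members, so
    the comparison reads on actual expansions rather than the sea of naive
    singletons; pass ``min_size=1`` to keep every clone.
    """
    rows = []
    for group, cs in clonesets_by_group.items():
        for c in cs.clones:
            if c.size < min_size:
                continue
            rows.append({"group": group, "clone_id": c.clone_id,
                         "size": c.size, "log10_size": float(np.log10(c.size))})
    df = pd.DataFrame(rows)
    report = None
    groups = sorted(clonesets_by_group)
    if len(groups) == 2:
        a = df.loc[df["group"] == groups[0], "log10_size"].to_numpy()
        b = df.loc[df["group"] == groups[1], "log10_size"].to_numpy()
        if len(a) >= 1 and len(b) >= 1:
            report = mann_whitney(a, b)
    return df, report


@dataclass
class LogoMatrix:
    """Signed Kullback-Leibler sequence logo.

    ``weights`` is positions x amino acids in bits; letters enriched over
    the background have positive weight, depleted letters negative (they
    plot below the axis).
    """

    weights: pd.DataFrame
    background: pd.Series

    @property
    def positions(self) -> list[int]:
        return list(self.weights.index)


def kl_logo(
    windows: list[str],
    background: pd.Series | dict | None = None,
    pseudocount: float = 1.0,
) -> LogoMatrix:
    """Kullback-Leibler logo of aligned equal-length amino-acid windows.

    Per position i and residue a, with observed count c, column total n and
    background frequency q_a::

        p = (c + pseudocount * q_a) / (n + pseudocount)
        weight(i, a) = p * log2(p / q_a)

    so weight is positive iff p > q_a.  The background defaults to uniform
    (1/20) and must be strictly positive, summing to 1.  Letters outside the
    20-residue alphabet (e.g. X) are ignored in the counts.
    """
    if not windows:
        raise ValueError("no windows")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("windows must all have equal length")
    if background is None:
        background = pd.Series(1.0 / 20, index=AMINO_ACIDS)
    else:
        background = pd.Series(background).reindex(AMINO_ACIDS)
        if background.isna().any() or (background <= 0).any():
            raise ValueError("background must be strictly positive over the 20 residues")
        if not np.isclose(background.sum(), 1.0):
            raise ValueError("background must sum to 1")
    q = background.to_numpy()
    weights = np.zeros((L, 20))
    for i in range(L):
        col = Counter(w[i] for w in windows)
        c = np.array([col.get(a, 0) for a in AMINO_ACIDS], dtype=float)
        n = c.sum()
        p = (c + pseudocount * q) / (n + pseudocount)
        weights[i] = p * np.log2(p / q)
    wdf = pd.DataFrame(weights, index=pd.RangeIndex(1, L + 1, name="position"),
                       columns=AMINO_ACIDS)
    return LogoMatrix(weights=wdf, background=background)
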