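"""Synthetic bone-marrow expression and repertoire data with planted truth.

The generator emulates the measurement situation of a spontaneous
plasma-cell-malignancy mouse study: a bone-marrow cell mixture whose plasma
cells split into malignant and nonmalignant subpopulations differing in two
signature gene sets; a heavy-chain repertoire mixing a diverse, essentially
unmutated IgM naive compartment with large, class-switched, highly mutated
expanded clones — among them one canonical antigen-driven clone using a
VH1-72 analog whose CDR1 window position 8 (VH amino acid 33) carries the
affinity-enhancing W->L mutation in a configurable fraction of members —
and a treatment effect that depletes malignant cells and expanded clones by
a configurable factor while leaving the naive compartment untouched.

Every planted quantity is recorded in a :class:`SyntheticTruth` so that
downstream recovery can be checked against ground truth.  All outputs are
pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GermlineSegment,
    Rearrangement,
    read_germline_fasta,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_expression",
    "generate_repertoire",
    "apply_treatment",
    "generate_dataset",
    "load_packaged_germlines",
    "CELL_TYPES",
    "MARKER_GENES",
]

CELL_TYPES = ["plasma", "b_cell", "t_nk", "granulocyte", "other"]

#: Canonical marker genes elevated in (and exclusive to) each cell type.
MARKER_GENES = {
    "plasma": ["Sdc1", "Xbp1", "Prdm1"],
    "b_cell": ["Cd19", "Cd79a", "Ms4a1"],
    "t_nk": ["Cd3e", "Nkg7"],
    "granulocyte": ["S100a8", "S100a9"],
    "other": [],
}
MITO_GENES = ["mt-Co1", "mt-Nd1"]

_ISOTYPE_TO_CCALL = {
    "IgM": "IGHM", "IgD": "IGHD", "IgG1": "IGHG1", "IgG2b": "IGHG2B",
    "IgG2c": "IGHG2C", "IgG3": "IGHG3", "IgA": "IGHA", "IgE": "IGHE",
}
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


def _default_naive_isotypes() -> dict:
    return {"IgM": 0.82, "IgD": 0.10, "IgG3": 0.03, "IgG1": 0.02,
            "IgG2b": 0.02, "IgG2c": 0.01}


def _default_expanded_isotypes() -> dict:
    return {"IgG1": 0.40, "IgG2b": 0.15, "IgG2c": 0.15, "IgG3": 0.05,
            "IgA": 0.15, "IgM": 0.10}


def _default_proportions() -> dict:
    return {"plasma": 0.15, "b_cell": 0.30, "t_nk": 0.20,
            "granulocyte": 0.25, "other": 0.10}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Defaults describe the untreated arm of a marrow with substantial
    malignant involvement; treatment divides malignant plasma-cell numbers
    and expanded-clone sizes by ``depletion_factor`` and shifts the
    canonical clone's W33L fraction from ``w33l_fraction_untreated`` to
    ``w33l_fraction_treated``.
    """

    # expression side
    n_cells_per_sample: int = 800
    n_genes: int = 1500
    cell_type_proportions: dict = field(default_factory=_default_proportions)
    malignant_fraction_untreated: float = 0.5
    signature_effect: float = 2.0          # log-scale shift on signature genes
    library_size_mean: float = 5000.0      # expected counts per cell
    dispersion: float = 0.5                # negative-binomial overdispersion
    n_signature_genes: int = 50
    n_samples_untreated: int = 5
    n_samples_treated: int = 6
    # repertoire side
    repertoire_cells_per_sample: int = 9000
    clone_count: int = 5
    clone_size_distribution: float = 2.0   # power-law exponent of clone sizes
    clone_size_min: int = 72
    clone_size_max: int = 300
    canonical_clone_size: int = 200        # members of the antigen-driven clone
    shm_rate_naive: float = 0.002          # per-site mutation probability
    shm_rate_expanded: float = 0.05
    isotype_probs_naive: dict = field(default_factory=_default_naive_isotypes)
    isotype_probs_expanded: dict = field(default_factory=_default_expanded_isotypes)
    cdr3_variant_prob: float = 0.2         # per-member chance of 1 CDR3 substitution
    w33l_fraction_untreated: float = 0.56
    w33l_fraction_treated: float = 0.10
    # treatment
    depletion_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        props = self.cell_type_proportions
        if set(props) != set(CELL_TYPES):
            raise ConfigError(f"cell_type_proportions must cover {CELL_TYPES}")
        if any(not 0 <= v <= 1 for v in props.values()):
            raise ConfigError("proportions must lie in [0, 1]")
        if not math.isclose(sum(props.values()), 1.0, abs_tol=1e-6):
            raise ConfigError("cell_type_proportions must sum to 1")
        for name in ("isotype_probs_naive", "isotype_probs_expanded"):
            d = getattr(self, name)
            if not math.isclose(sum(d.values()), 1.0, abs_tol=1e-6):
                raise ConfigError(f"{name} must sum to 1")
        if self.depletion_factor < 1:
            raise ConfigError("depletion_factor must be >= 1")
        for name in ("malignant_fraction_untreated", "shm_rate_naive",
                     "shm_rate_expanded", "w33l_fraction_untreated",
                     "w33l_fraction_treated", "cdr3_variant_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if 2 * self.n_signature_genes + 20 > self.n_genes:
            raise ConfigError("n_genes too small for the two signature sets")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated dataset."""

    cells: pd.DataFrame | None = None           # cell_id, cell_type, malignant
    rearrangements: pd.DataFrame | None = None  # per-record clone/mutation truth
    clones: pd.DataFrame | None = None          # per-clone size / depletion
    gene_sets: dict | None = None               # name -> GeneSet

    def to_json(self, path) -> None:
        import json

        payload = {}
        if self.cells is not None:
            payload["cells"] = self.cells.to_dict(orient="list")
        if self.rearrangements is not None:
            df = self.rearrangements.copy()
            df["mutated_positions"] = df["mutated_positions"].apply(
                lambda v: list(map(int, v))
            )
            payload["rearrangements"] = df.to_dict(orient="list")
        if self.clones is not None:
            payload["clones"] = self.clones.to_dict(orient="list")
        if self.gene_sets is not None:
            payload["gene_sets"] = {k: v.genes for k, v in self.gene_sets.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    rearrangements: list[Rearrangement]
    truth: SyntheticTruth
    germlines: dict[str, GermlineSegment]
    gene_sets: dict


def load_packaged_germlines() -> tuple[dict[str, GermlineSegment], dict[str, GermlineSegment]]:
    """Load the packaged toy germline V and J segment sets."""
    data = resources.files("clonal_surveil").joinpath("data")
    v = read_germline_fasta(str(data / "germline_v.fasta"))
    j = read_germline_fasta(str(data / "germline_j.fasta"))
    return v, j


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _sample_names(cfg: SimulationConfig) -> list[tuple[str, str]]:
    names = [(f"U{i + 1}", "untreated") for i in range(cfg.n_samples_untreated)]
    names += [(f"T{i + 1}", "treated") for i in range(cfg.n_samples_treated)]
    return names


def _type_counts(cfg: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of cells to types (conserves total)."""
    n = cfg.n_cells_per_sample
    raw = {t: cfg.cell_type_proportions[t] * n for t in CELL_TYPES}
    counts = {t: int(math.floor(v)) for t, v in raw.items()}
    short = n - sum(counts.values())
    for t in sorted(CELL_TYPES, key=lambda t: raw[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    return counts


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], dict]:
    markers = [g for t in CELL_TYPES for g in MARKER_GENES[t]]
    n_generic = cfg.n_genes - len(markers) - len(MITO_GENES)
    generic = [f"G{i + 1:04d}" for i in range(n_generic)]
    genes = markers + MITO_GENES + generic
    k = cfg.n_signature_genes
    gene_sets = {
        "malignant": GeneSet("malignant", generic[:k]),
        "nonmalignant": GeneSet("nonmalignant", generic[k:2 * k]),
    }
    return genes, gene_sets


def _nb_counts(rng, libs: np.ndarray, weights: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts for one homogeneous block."""
    w = weights / weights.sum()
    mu = libs[:, None] * w[None, :]
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    else:
        lam = mu
    return rng.poisson(lam)


def generate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate the cells x genes count matrix with planted malignancy.

    Counts follow a negative-binomial model with per-cell library size and
    per-gene base expression; cell-type marker genes are elevated in their
    type and silent elsewhere; malignant plasma cells get the signature
    shift on the malignant gene set, nonmalignant plasma cells on the
    nonmalignant set.  Treated samples carry a malignant plasma-cell
    fraction reduced by ``depletion_factor``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    genes, gene_sets = _gene_names(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mito_idx = [gene_pos[g] for g in MITO_GENES]
    base[mito_idx] = np.median(base) * 3  # modest ubiquitous mito signal
    mal_idx = np.array([gene_pos[g] for g in gene_sets["malignant"].genes])
    nml_idx = np.array([gene_pos[g] for g in gene_sets["nonmalignant"].genes])
    marker_idx = {t: [gene_pos[g] for g in MARKER_GENES[t]] for t in CELL_TYPES}
    all_marker_idx = [i for idx in marker_idx.values() for i in idx]

    type_weights = {}
    for t in CELL_TYPES:
        w = base.copy()
        w[all_marker_idx] = 0.0
        if marker_idx[t]:
            w[marker_idx[t]] = np.median(base) * 40
        type_weights[t] = w

    counts_per_type = _type_counts(cfg)
    blocks, cell_ids, ann_rows, truth_rows = [], [], [], []
    for sample, group in _sample_names(cfg):
        mal_frac = cfg.malignant_fraction_untreated
        if group == "treated":
            mal_frac = mal_frac / cfg.depletion_factor
        cell_counter = 0
        for t in CELL_TYPES:
            n_t = counts_per_type[t]
            if n_t == 0:
                continue
            if t == "plasma":
                n_mal = int(round(mal_frac * n_t))
                subblocks = [("malignant", n_mal), ("nonmalignant", n_t - n_mal)]
            else:
                subblocks = [(None, n_t)]
            for state, n_b in subblocks:
                if n_b == 0:
                    continue
                w = type_weights[t].copy()
                if state == "malignant":
                    w[mal_idx] *= math.exp(cfg.signature_effect)
                elif state == "nonmalignant":
                    w[nml_idx] *= math.exp(cfg.signature_effect)
                libs = rng.lognormal(
                    mean=math.log(cfg.library_size_mean) - 0.045, sigma=0.3, size=n_b
                )
                blocks.append(sp.csr_matrix(_nb_counts(rng, libs, w, cfg.dispersion)))
                for _ in range(n_b):
                    cid = f"{sample}_c{cell_counter:05d}"
                    cell_counter += 1
                    cell_ids.append(cid)
                    ann_rows.append(
                        {"cell_id": cid, "sample_id": sample, "group": group,
                         "cell_type": t}
                    )
                    truth_rows.append(
                        {"cell_id": cid, "cell_type": t,
                         "malignant": state == "malignant"}
                    )
    counts = sp.vstack(blocks, format="csr")
    counts.data = counts.data.astype(np.int64)
    matrix = ExpressionMatrix(genes=genes, cells=cell_ids, counts=counts, layer="raw")
    annotation = pd.DataFrame(ann_rows)
    truth = SyntheticTruth(cells=pd.DataFrame(truth_rows), gene_sets=gene_sets)
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# repertoire
# ---------------------------------------------------------------------------

def _truncated_power_law(rng, n: int, exponent: float, lo: int, hi: int) -> np.ndarray:
    """Integer draws with pdf ~ s^-exponent on [lo, hi] (inverse CDF)."""
    u = rng.random(n)
    a = exponent
    if math.isclose(a, 1.0):
        s = lo * (hi / lo) ** u
    else:
        lo_p, hi_p = lo ** (1 - a), hi ** (1 - a)
        s = (lo_p - u * (lo_p - hi_p)) ** (1.0 / (1 - a))
    return np.clip(np.round(s).astype(int), lo, hi)


def _mutate_block(
    rng, germ: str, n: int, rate: float, protect: np.ndarray | None = None
) -> tuple[list[str], list[np.ndarray]]:
    """Mutate ``n`` copies of a germline sequence at per-site ``rate``.

    ``protect`` masks positions never mutated.  Returns sequences and the
    mutated position arrays.
    """
    arr = np.frombuffer(germ.encode(), dtype=np.uint8)
    L = len(arr)
    # work in base indices 0..3 so "mutate to a different base" is an offset
    lut = np.zeros(256, dtype=np.uint8)
    lut[_NT] = np.arange(4)
    germ_idx = lut[arr]
    mask = rng.random((n, L)) < rate
    if protect is not None:
        mask[:, protect] = False
    seqs_idx = np.tile(germ_idx, (n, 1))
    rows, cols = np.nonzero(mask)
    if len(rows):
        offsets = rng.integers(1, 4, size=len(rows)).astype(np.uint8)
        seqs_idx[rows, cols] = (seqs_idx[rows, cols] + offsets) % 4
    chars = _NT[seqs_idx]
    out_seqs = [chars[i].tobytes().decode() for i in range(n)]
    out_pos = [np.flatnonzero(mask[i]) for i in range(n)]
    return out_seqs, out_pos


def _random_cdr3(rng, length: int) -> str:
    aas = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    return rng.choice(aas, size=length).tobytes().decode()


def _cdr3_variant(rng, ancestor: str, prob: float) -> str:
    if rng.random() >= prob:
        return ancestor
    pos = int(rng.integers(len(ancestor)))
    aas = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ancestor[pos]]
    return ancestor[:pos] + str(rng.choice(aas)) + ancestor[pos + 1:]


_NAIVE_CDR3_LENGTHS = np.arange(9, 16)
_NAIVE_CDR3_WEIGHTS = np.array([0.05, 0.10, 0.20, 0.30, 0.20, 0.10, 0.05])
_EXPANDED_CDR3_LENGTHS = np.array([7, 8, 9])
_EXPANDED_CDR3_WEIGHTS = np.array([0.2, 0.6, 0.2])


def generate_repertoire(
    cfg: SimulationConfig,
    annotation: pd.DataFrame,
    germline_v: dict[str, GermlineSegment] | None = None,
    canonical_v: str = "VH1-72",
) -> tuple[list[Rearrangement], SyntheticTruth]:
    """Generate heavy-chain repertoires for every sample in the annotation.

    Untreated samples mix a diverse naive compartment (uniform V/J over the
    non-canonical segments, IgM-dominant isotypes, mutations at
    ``shm_rate_naive``) with ``clone_count`` expanded clones sharing a
    (V, J, ancestor CDR3) and mutating at ``shm_rate_expanded``; members stay
    within one substitution of the ancestor CDR3.  The largest clone is the
    canonical antigen-driven clone: it uses the VH1-72 analog (reserved for
    it) and carries W->L at CDR1 window position 8 in
    ``w33l_fraction_untreated`` of its members.  Treated samples are
    generated identically, then passed through :func:`apply_treatment`.
    """
    if germline_v is None:
        germline_v, _ = load_packaged_germlines()
    if canonical_v not in germline_v:
        raise ConfigError(f"germline set lacks the canonical segment {canonical_v!r}")
    j_names = ["JH1", "JH2", "JH3", "JH4"]
    other_v = sorted(v for v in germline_v if v != canonical_v)
    if not other_v:
        raise ConfigError("germline set needs at least one non-canonical V segment")

    canon = germline_v[canonical_v]
    if canon.cdr1_aa_start is None:
        raise ConfigError(f"{canonical_v} germline lacks cdr1_aa_start annotation")
    w33_codon = slice((canon.cdr1_aa_start + 8 - 2) * 3, (canon.cdr1_aa_start + 8 - 1) * 3)
    protect = np.arange(w33_codon.start, w33_codon.stop)

    from zlib import crc32  # stable per-sample sub-seeds (hash() is salted)

    samples = (
        annotation[["sample_id", "group"]].drop_duplicates().itertuples(index=False)
    )
    all_records: list[Rearrangement] = []
    rear_rows: list[dict] = []
    clone_rows: list[dict] = []
    for sample_id, group in samples:
        sub = crc32(str(sample_id).encode()) % (2**31)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, sub]))
        records, rrows, crows = _one_sample_repertoire(
            cfg, sample_id, rng, germline_v, canonical_v, other_v, j_names,
            protect, w33_codon,
        )
        if group == "treated":
            records, rrows, crows = apply_treatment(
                records, rrows, crows, cfg,
                rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, sub])),
            )
        all_records.extend(records)
        rear_rows.extend(rrows)
        clone_rows.extend(crows)

    truth = SyntheticTruth(
        rearrangements=pd.DataFrame(rear_rows),
        clones=pd.DataFrame(clone_rows),
    )
    return all_records, truth


def _one_sample_repertoire(
    cfg, sample_id, rng, germline_v, canonical_v, other_v, j_names, protect, w33_codon
):
    records: list[Rearrangement] = []
    rear_rows: list[dict] = []
    clone_rows: list[dict] = []

    # clone 0 is the designated antigen-driven clone with a controlled size;
    # the remaining expansions draw power-law sizes
    sizes = np.concatenate([
        [cfg.canonical_clone_size],
        _truncated_power_law(
            rng, cfg.clone_count - 1, cfg.clone_size_distribution,
            cfg.clone_size_min, cfg.clone_size_max,
        ),
    ])
    n_expanded = int(sizes.sum())
    n_naive = cfg.repertoire_cells_per_sample - n_expanded
    if n_naive < 0:
        raise ConfigError(
            "expanded clones exceed repertoire_cells_per_sample; "
            "reduce clone_count or clone sizes"
        )

    iso_exp = list(cfg.isotype_probs_expanded.items())
    iso_naive = list(cfg.isotype_probs_naive.items())
    counter = 0

    for k, size in enumerate(sizes):
        canonical = k == 0
        v_name = canonical_v if canonical else str(rng.choice(other_v))
        j_name = str(rng.choice(j_names))
        germ = germline_v[v_name].seq
        cdr3_len = int(rng.choice(_EXPANDED_CDR3_LENGTHS, p=_EXPANDED_CDR3_WEIGHTS))
        ancestor = _random_cdr3(rng, cdr3_len)
        isotype = "IgG1" if canonical else str(
            rng.choice([i for i, _ in iso_exp], p=[p for _, p in iso_exp])
        )
        seqs, poss = _mutate_block(
            rng, germ, int(size), cfg.shm_rate_expanded,
            protect=protect if canonical else None,
        )
        w33l_flags = np.zeros(int(size), dtype=bool)
        if canonical:
            n_w33l = int(round(cfg.w33l_fraction_untreated * size))
            w33l_flags[rng.permutation(int(size))[:n_w33l]] = True
        clone_label = f"{sample_id}:clone{k}"
        for i in range(int(size)):
            seq = seqs[i]
            pos = poss[i]
            if canonical and w33l_flags[i]:
                seq = seq[:w33_codon.start] + "CTG" + seq[w33_codon.stop:]
                mutated = np.flatnonzero(
                    np.frombuffer(seq.encode(), np.uint8)
                    != np.frombuffer(germ.encode(), np.uint8)
                )
                pos = mutated
            cid = f"{sample_id}_r{counter:05d}"
            counter += 1
            records.append(
                Rearrangement(
                    cell_id=cid,
                    v_call=v_name,
                    j_call=j_name,
                    c_call=_ISOTYPE_TO_CCALL[isotype],
                    cdr3_aa=_cdr3_variant(rng, ancestor, cfg.cdr3_variant_prob),
                    v_seq_aligned=seq,
                    germline_v_aligned=germ,
                    sample_id=sample_id,
                )
            )
            rear_rows.append(
                {"cell_id": cid, "sample_id": sample_id, "clone_label": clone_label,
                 "expanded": True, "canonical": canonical,
                 "w33l": bool(canonical and w33l_flags[i]),
                 "germline_v": v_name, "n_mutations": len(pos),
                 "mutated_positions": pos}
            )
        clone_rows.append(
            {"sample_id": sample_id, "clone_label": clone_label, "v_call": v_name,
             "j_call": j_name, "ancestor_cdr3": ancestor, "size": int(size),
             "canonical": canonical, "isotype": isotype, "depleted_to": int(size)}
        )

    # naive compartment: diverse, IgM-dominant, essentially unmutated
    naive_v = rng.choice(other_v, size=n_naive)
    naive_j = rng.choice(j_names, size=n_naive)
    naive_iso = rng.choice(
        [i for i, _ in iso_naive], size=n_naive, p=[p for _, p in iso_naive]
    )
    naive_len = rng.choice(_NAIVE_CDR3_LENGTHS, size=n_naive, p=_NAIVE_CDR3_WEIGHTS)
    # group by germline so mutation masks are drawn in vectorized blocks
    by_v: dict[str, list[int]] = {}
    for i, v in enumerate(naive_v):
        by_v.setdefault(str(v), []).append(i)
    naive_seqs = [None] * n_naive
    naive_pos = [None] * n_naive
    for v_name in sorted(by_v):
        idx = by_v[v_name]
        seqs, poss = _mutate_block(rng, germline_v[v_name].seq, len(idx),
                                   cfg.shm_rate_naive)
        for j, i in enumerate(idx):
            naive_seqs[i] = seqs[j]
            naive_pos[i] = poss[j]
    for i in range(n_naive):
        cid = f"{sample_id}_r{counter:05d}"
        counter += 1
        records.append(
            Rearrangement(
                cell_id=cid,
                v_call=str(naive_v[i]),
                j_call=str(naive_j[i]),
                c_call=_ISOTYPE_TO_CCALL[str(naive_iso[i])],
                cdr3_aa=_random_cdr3(rng, int(naive_len[i])),
                v_seq_aligned=naive_seqs[i],
                germline_v_aligned=germline_v[str(naive_v[i])].seq,
                sample_id=sample_id,
            )
        )
        rear_rows.append(
            {"cell_id": cid, "sample_id": sample_id,
             "clone_label": f"{sample_id}:naive{i}", "expanded": False,
             "canonical": False, "w33l": False, "germline_v": str(naive_v[i]),
             "n_mutations": len(naive_pos[i]), "mutated_positions": naive_pos[i]}
        )
    return records, rear_rows, clone_rows


def apply_treatment(
    records: list[Rearrangement],
    rear_rows: list[dict],
    clone_rows: list[dict],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Deplete expanded clones of one sample by ``depletion_factor``.

    Each expanded clone's member count is divided by the depletion factor
    (round half-up, floor 0); the naive compartment is untouched.  Survivors
    of the canonical clone are chosen so that the planted W33L fraction
    becomes ``w33l_fraction_treated``.  Seed-deterministic given ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    d = cfg.depletion_factor
    by_clone: dict[str, list[int]] = {}
    for i, row in enumerate(rear_rows):
        if row["expanded"]:
            by_clone.setdefault(row["clone_label"], []).append(i)

    keep = np.ones(len(records), dtype=bool)
    new_sizes: dict[str, int] = {}
    for label, idx in sorted(by_clone.items()):
        size = len(idx)
        new_size = max(0, int(math.floor(size / d + 0.5)))
        new_sizes[label] = new_size
        canonical = rear_rows[idx[0]]["canonical"]
        if canonical:
            n_w = int(round(cfg.w33l_fraction_treated * new_size))
            w_idx = [i for i in idx if rear_rows[i]["w33l"]]
            o_idx = [i for i in idx if not rear_rows[i]["w33l"]]
            n_w = min(n_w, len(w_idx))
            n_o = min(new_size - n_w, len(o_idx))
            chosen = list(rng.choice(w_idx, size=n_w, replace=False)) + list(
                rng.choice(o_idx, size=n_o, replace=False)
            )
        else:
            chosen = list(rng.choice(idx, size=new_size, replace=False))
        drop = set(idx) - set(int(i) for i in chosen)
        for i in drop:
            keep[i] = False

    new_records = [r for i, r in enumerate(records) if keep[i]]
    new_rear = [row for i, row in enumerate(rear_rows) if keep[i]]
    new_clones = []
    for row in clone_rows:
        row = dict(row)
        row["depleted_to"] = new_sizes.get(row["clone_label"], row["size"])
        new_clones.append(row)
    return new_records, new_rear, new_clones


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full paired dataset: expression + annotation + repertoire."""
    matrix, annotation, expr_truth = generate_expression(cfg)
    germline_v, _ = load_packaged_germlines()
    records, rep_truth = generate_repertoire(cfg, annotation, germline_v)
    truth = SyntheticTruth(
        cells=expr_truth.cells,
        rearrangements=rep_truth.rearrangements,
        clones=rep_truth.clones,
        gene_sets=expr_truth.gene_sets,
    )
    return SyntheticDataset(
        matrix=matrix,
        annotation=annotation,
        rearrangements=records,
        truth=truth,
        germlines=germline_v,
        gene_sets=expr_truth.gene_sets,
    )
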