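"""Identity-stratified profile-model library construction.

From a curated catalog of labeled enzyme sequences: greedy identity
clustering picks representatives; each representative is expanded against a
sequence database (homologues at E-value below a cutoff, binned by pairwise
identity on a 60-90% grid in 5% steps); each non-empty bin yields one
position-specific log-odds model labeled with the representative's plastic
type.

Identity here is the number of identical global-alignment columns divided by
the length of the shorter sequence (match +1 / mismatch 0 / linear gap -1
scoring). Greedy clustering processes records by descending length (ties:
lexicographic id) and joins the first representative matched at or above the
cutoff — a deterministic, oracle-checkable stand-in for the usual
heuristic clustering tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .synthetic import AA_INDEX, N_AA

#: the seven identity cutoffs used to stratify expanded homolog sets
IDENTITY_GRID: tuple[float, ...] = (0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90)

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class EnzymeRecord:
    id: str
    sequence: str
    plastic_type: str
    compound_class: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"record {self.id!r} has non-standard residues {sorted(bad)}")
        if not self.plastic_type:
            raise ValueError(f"record {self.id!r} lacks a plastic type")


@dataclass
class SequenceCluster:
    representative_id: str
    member_ids: list[str]
    identity_cutoff: float


@dataclass
class ProfileModelGroup:
    """One profile model: a representative's expanded sequence set at one
    identity cutoff, with its position-specific log-odds payload."""

    model_id: str
    representative_id: str
    identity_bin: float
    member_sequences: list[str]
    plastic_type: str
    compound_class: str
    model_payload: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not any(abs(self.identity_bin - c) < 1e-9 for c in IDENTITY_GRID):
            raise ValueError(f"identity_bin {self.identity_bin} not on the grid")
        if not self.member_sequences:
            raise ValueError("a model needs at least one member sequence")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def _best_alignment(a: str, b: str):
    return _ALIGNER.align(a, b)[0]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned columns, shorter-sequence denominator."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _best_alignment(a, b)
    ident = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        sa, sb = a[t0:t1], b[q0:q1]
        ident += sum(x == y for x, y in zip(sa, sb))
    return ident / min(len(a), len(b))


def cluster_sequences(
    records: Sequence[EnzymeRecord], cutoff: float
) -> list[SequenceCluster]:
    """Greedy incremental clustering at an identity cutoff.

    Records are visited by descending length, ties broken by lexicographic
    id; each joins the first existing cluster whose representative matches
    at >= cutoff, else founds a new one. The clusters partition the input.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[SequenceCluster] = []
    reps: list[EnzymeRecord] = []
    for rec in order:
        placed = False
        for cl, rep in zip(clusters, reps):
            if pairwise_identity(rec.sequence, rep.sequence) >= cutoff:
                cl.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(rec.id, [rec.id], cutoff))
            reps.append(rec)
    return clusters


def expand_homologs(
    representatives: Sequence[EnzymeRecord],
    database: Sequence[tuple[str, str]],
    evalue_max: float = 1e-10,
    identity_grid: Sequence[float] = IDENTITY_GRID,
    mode: str = "cumulative",
    n_decoys: int = 10_000,
    seed: int = 0,
) -> dict[str, dict[float, list[tuple[str, str]]]]:
    """Per-representative, per-identity-bin homolog sets.

    Each representative is searched against the database with the built-in
    decoy-calibrated scorer (single-sequence model per representative);
    database sequences with E-value < evalue_max are assigned to identity
    bins. In ``cumulative`` mode (default) a sequence enters every bin whose
    cutoff its identity meets; in ``bracket`` mode only the highest such
    bin. The representative itself is a member of every bin.
    """
    from . import search as _search

    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    if not database:
        raise ValueError("database must be non-empty")
    if mode not in ("cumulative", "bracket"):
        raise ValueError(f"unknown bin mode {mode!r}")

    grid = sorted(identity_grid)
    seqs_by_id = dict(database)
    db_ids = [g for g, _ in database]
    decoys = _search.make_decoys([s for _, s in database], n_decoys, seed)
    grouped_db = _search._encode_batchable([s for _, s in database])
    grouped_decoys = _search._encode_batchable(decoys)
    out: dict[str, dict[float, list[tuple[str, str]]]] = {}
    for rep in representatives:
        model = build_model_group([rep.sequence], rep, cutoff=grid[0])
        matrix = model.model_payload["matrix"]
        scores = _search._window_scores_grouped(matrix, grouped_db, len(database))
        decoy_scores = _search._window_scores_grouped(matrix, grouped_decoys, len(decoys))
        calib = _search.DecoyCalibration.fit(decoy_scores, n_catalog=len(database))
        evalues = calib.evalues(scores)
        scored = list(zip(db_ids, scores.tolist(), evalues.tolist()))
        bins: dict[float, list[tuple[str, str]]] = {
            c: [(rep.id, rep.sequence)] for c in grid
        }
        for gene_id, _score, evalue in scored:
            if gene_id == rep.id or evalue >= evalue_max:
                continue
            ident = pairwise_identity(rep.sequence, seqs_by_id[gene_id])
            qualifying = [c for c in grid if ident >= c]
            if not qualifying:
                continue
            targets = qualifying if mode == "cumulative" else [max(qualifying)]
            for c in targets:
                bins[c].append((gene_id, seqs_by_id[gene_id]))
        out[rep.id] = bins
    return out


def build_model_group(
    bin_sequences: Sequence[str],
    representative: EnzymeRecord,
    cutoff: float,
    background: np.ndarray | None = None,
) -> ProfileModelGroup:
    """Position-specific log-odds model over the representative's columns.

    Every member is globally aligned to the representative; member residues
    that align to a representative column are counted there (gaps
    contribute nothing). Column probabilities use plus-one pseudocounts,
    p_col(aa) = (count + 1) / (n_obs + 20), and the payload stores
    log2(p_col / q) against the background q (uniform by default).
    """
    if not bin_sequences:
        raise ValueError("a model needs at least one member sequence")
    q = np.full(N_AA, 1.0 / N_AA) if background is None else np.asarray(background, float)
    rep_seq = representative.sequence
    L = len(rep_seq)
    counts = np.zeros((L, N_AA), dtype=float)
    nobs = np.zeros(L, dtype=float)
    for seq in bin_sequences:
        if seq == rep_seq:
            cols = range(L)
            residues = rep_seq
            for i, aa in zip(cols, residues):
                if aa in AA_INDEX:
                    counts[i, AA_INDEX[aa]] += 1.0
                    nobs[i] += 1.0
            continue
        aln = _best_alignment(rep_seq, seq)
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            for off in range(t1 - t0):
                aa = seq[q0 + off]
                if aa in AA_INDEX:
                    counts[t0 + off, AA_INDEX[aa]] += 1.0
                    nobs[t0 + off] += 1.0
    probs = (counts + 1.0) / (nobs[:, None] + N_AA)
    matrix = np.log2(probs / q[None, :])
    model_id = f"{representative.id}|c{int(round(cutoff * 100)):02d}"
    return ProfileModelGroup(
        model_id=model_id,
        representative_id=representative.id,
        identity_bin=round(cutoff, 2),
        member_sequences=list(bin_sequences),
        plastic_type=representative.plastic_type,
        compound_class=representative.compound_class,
        model_payload={"matrix": matrix, "background": q, "length": L, "probs": probs},
    )


def build_library(
    representatives: Sequence[EnzymeRecord],
    expanded: Mapping[str, Mapping[float, Sequence[tuple[str, str]]]],
) -> list[ProfileModelGroup]:
    """One model per representative per non-empty identity bin."""
    rep_by_id = {r.id: r for r in representatives}
    models: list[ProfileModelGroup] = []
    for rep_id in sorted(expanded):
        rep = rep_by_id[rep_id]
        for cutoff in sorted(expanded[rep_id]):
            members = [seq for _gid, seq in expanded[rep_id][cutoff]]
            if members:
                models.append(build_model_group(members, rep, cutoff))
    return models


def library_manifest(models: Sequence[ProfileModelGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model_id": [m.model_id for m in models],
            "representative_id": [m.representative_id for m in models],
            "identity_bin": [m.identity_bin for m in models],
            "n_members": [len(m.member_sequences) for m in models],
            "plastic_type": [m.plastic_type for m in models],
            "compound_class": [m.compound_class for m in models],
        }
    )


def write_library(models: Sequence[ProfileModelGroup], out_dir) -> None:
    """Model library directory: manifest TSV plus one payload TSV per model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library_manifest(models).to_csv(out / "manifest.tsv", sep="\t", index=False)
    for m in models:
        safe = m.model_id.replace("|", "_")
        np.savetxt(
            out / f"{safe}.matrix.tsv",
            m.model_payload["matrix"],
            delimiter="\t",
            fmt="%.8g",
        )


def catalog_from_tables(
    fasta_records: Sequence[tuple[str, str]], labels: pd.DataFrame
) -> list[EnzymeRecord]:
    """Join a curated FASTA with its label table (id, plastic_type,
    compound_class, species) into EnzymeRecords."""
    lab = labels.set_index("id")
    records = []
    for rid, seq in fasta_records:
        row = lab.loc[rid]
        records.append(
            EnzymeRecord(
                id=rid,
                sequence=seq,
                plastic_type=str(row["plastic_type"]),
                compound_class=str(row["compound_class"]),
                species=str(row["species"]) if "species" in lab.columns else None,
            )
        )
    return records
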