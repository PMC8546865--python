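"""Scoring gene catalogs against the model library.

The built-in scorer computes, for each gene and model, the best ungapped
window log-odds score (bits) of the gene against the model's
position-specific matrix. Statistical calibration is empirical: a pool of
seeded residue-shuffled decoys drawn from the catalog is scored against each
model, and

    E(s) = N_catalog * (1 + #{decoy scores >= s}) / (1 + N_decoys)

inside the decoy score range. Above the largest decoy score the plus-one
numerator would otherwise floor the E-value at N_catalog/(1+N_decoys); there
the survival function is continued with an exponential tail whose rate is
the maximum-likelihood fit to the decoy exceedances over their 90th
percentile. This keeps E(s) non-increasing, strictly positive, and able to
certify strong matches at the stringent E-value cutoffs the filtering stage
uses, while remaining purely decoy-driven.

External per-target tabular search output (whitespace-delimited, '#'
comments; target name, accession, query name, accession, full-sequence
E-value, full-sequence score, ...) can be ingested instead of the built-in
scorer, so a standard profile-search tool can stand behind this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library import ProfileModelGroup
from .synthetic import AA_INDEX

HIT_COLUMNS = ["gene_id", "sample_id", "model_id", "bit_score", "evalue", "origin"]

_MIN_EVALUE = 1e-300


@dataclass
class Hit:
    gene_id: str
    sample_id: str
    model_id: str
    bit_score: float
    evalue: float
    origin: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if not np.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")
        if self.origin not in ("environmental", "control"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class HitTable:
    """Hits plus provenance (scorer name, cutoffs, library info)."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"hit table missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.provenance.items()):
                fh.write(f"#{k}={v}\n")
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "HitTable":
        prov = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                prov[key] = val
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh, sep="\t")
        frame = frame.astype({"bit_score": float, "evalue": float})
        return cls(frame, prov)


# ---------------------------------------------------------------------------
# window scoring

def _encode_batchable(seqs: Sequence[str]) -> dict[int, tuple[list[int], np.ndarray]]:
    """Group encoded sequences by length: {length: (indices, matrix)}."""
    by_len: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    for i, s in enumerate(seqs):
        enc = np.fromiter((AA_INDEX.get(c, 0) for c in s), dtype=np.int64, count=len(s))
        by_len.setdefault(len(s), ([], []))[0].append(i)
        by_len[len(s)][1].append(enc)
    return {L: (idx, np.vstack(rows)) for L, (idx, rows) in by_len.items()}


def _window_scores_for_batch(matrix: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Best ungapped window score of each row of ``batch`` against the model.

    If a sequence is at least as long as the model, the model slides along
    the sequence; shorter sequences slide inside the model.
    """
    Lm = matrix.shape[0]
    n, Ls = batch.shape
    if Ls >= Lm:
        nwin = Ls - Lm + 1
        acc = np.zeros((n, nwin))
        for j in range(Lm):
            acc += matrix[j, batch[:, j : j + nwin]]
        return acc.max(axis=1)
    nwin = Lm - Ls + 1
    acc = np.zeros((n, nwin))
    for j in range(Ls):
        acc += matrix[j : j + nwin, batch[:, j]].T
    return acc.max(axis=1)


def _window_scores_grouped(
    matrix: np.ndarray, grouped: dict[int, tuple[list[int], np.ndarray]], n: int
) -> np.ndarray:
    out = np.empty(n)
    for _L, (idx, batch) in grouped.items():
        out[np.asarray(idx)] = _window_scores_for_batch(matrix, batch)
    return out


def window_scores(model: ProfileModelGroup, seqs: Sequence[str]) -> np.ndarray:
    matrix = model.model_payload["matrix"]
    return _window_scores_grouped(matrix, _encode_batchable(seqs), len(seqs))


def make_decoys(
    seqs: Sequence[str], n_decoys: int, seed: int
) -> list[str]:
    """Seeded residue shuffles of catalog genes (cycled/resampled to size)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    picks = rng.integers(0, len(seqs), size=n_decoys)
    out = []
    for p in picks:
        chars = np.array(list(seqs[p]))
        out.append("".join(rng.permutation(chars)))
    return out


@dataclass
class DecoyCalibration:
    """Empirical survival of decoy scores with an exponential upper tail."""

    sorted_scores: np.ndarray
    n_catalog: int
    tail_beta: float

    @classmethod
    def fit(cls, decoy_scores: np.ndarray, n_catalog: int) -> "DecoyCalibration":
        d = np.sort(np.asarray(decoy_scores, float))
        u = np.quantile(d, 0.9)
        exc = d[d > u] - u
        beta = float(exc.mean()) if exc.size else 1.0
        if not np.isfinite(beta) or beta <= 0:
            beta = 1.0
        return cls(d, n_catalog, beta)

    def evalues(self, scores: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, float)
        d = self.sorted_scores
        n_d = d.size
        n_ge = n_d - np.searchsorted(d, s, side="left")
        e = self.n_catalog * (1.0 + n_ge) / (1.0 + n_d)
        above = s > d[-1]
        if np.any(above):
            e_hi = self.n_catalog * 2.0 / (1.0 + n_d)
            with np.errstate(under="ignore"):
                e[above] = e_hi * np.exp(-(s[above] - d[-1]) / self.tail_beta)
        return np.maximum(e, _MIN_EVALUE)


def score_sequences(
    model: ProfileModelGroup,
    catalog: Sequence[tuple[str, str]],
    n_decoys: int = 10_000,
    seed: int = 0,
    decoy_scores: np.ndarray | None = None,
) -> list[tuple[str, float, float]]:
    """(gene_id, bit_score, evalue) for every catalog gene against one model."""
    ids = [g for g, _ in catalog]
    seqs = [s for _, s in catalog]
    scores = window_scores(model, seqs)
    if decoy_scores is None:
        decoys = make_decoys(seqs, n_decoys, seed)
        decoy_scores = window_scores(model, decoys)
    calib = DecoyCalibration.fit(decoy_scores, n_catalog=len(catalog))
    evals = calib.evalues(scores)
    return list(zip(ids, scores.tolist(), evals.tolist()))


def _default_sample_of(gene_id: str) -> str:
    return gene_id.rsplit("_g", 1)[0] if "_g" in gene_id else ""


def score_catalog(
    library: Sequence[ProfileModelGroup],
    catalog: Sequence[tuple[str, str]],
    evalue_report_max: float = 10.0,
    origin: str = "environmental",
    sample_of: Callable[[str], str] | Mapping[str, str] | None = None,
    n_decoys: int = 10_000,
    seed: int = 0,
) -> HitTable:
    """Raw hit table of a catalog against the whole library.

    One shared decoy pool (seeded shuffles of the catalog) is scored against
    every model; hits with E <= evalue_report_max are emitted. The raw table
    holds at most one row per (gene, model).
    """
    if not library:
        raise ValueError("library must be non-empty")
    for m in library:
        if "matrix" not in m.model_payload:
            raise ValueError(f"model {m.model_id} payload incompatible with built-in scorer")
    if sample_of is None:
        lookup: Callable[[str], str] = _default_sample_of
    elif callable(sample_of):
        lookup = sample_of
    else:
        mapping = dict(sample_of)
        lookup = lambda g: mapping[g]  # noqa: E731

    ids = [g for g, _ in catalog]
    seqs = [s for _, s in catalog]
    decoys = make_decoys(seqs, n_decoys, seed)
    grouped = _encode_batchable(seqs)
    grouped_decoys = _encode_batchable(decoys)
    rows = []
    for model in library:
        matrix = model.model_payload["matrix"]
        scores = _window_scores_grouped(matrix, grouped, len(seqs))
        decoy_scores = _window_scores_grouped(matrix, grouped_decoys, len(decoys))
        calib = DecoyCalibration.fit(decoy_scores, n_catalog=len(catalog))
        evals = calib.evalues(scores)
        keep = np.nonzero(evals <= evalue_report_max)[0]
        for i in keep:
            rows.append(
                (ids[i], lookup(ids[i]), model.model_id, float(scores[i]), float(evals[i]), origin)
            )
    frame = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(
        frame,
        provenance={
            "scorer": "ungapped-window-logodds",
            "n_models": len(library),
            "n_decoys": n_decoys,
            "evalue_report_max": evalue_report_max,
            "seed": seed,
        },
    )


def deduplicate_hits(raw: HitTable, per_model: bool = False) -> HitTable:
    """Keep the single best hit per gene: minimal E-value, ties broken by
    maximal bit score, then lexicographic model id.

    With ``per_model=True`` the best hit per (gene, model) pair is kept
    instead of one global winner per gene.
    """
    keys = ["gene_id", "model_id"] if per_model else ["gene_id"]
    frame = (
        raw.frame.sort_values(
            ["evalue", "bit_score", "model_id"], ascending=[True, False, True], kind="mergesort"
        )
        .drop_duplicates(keys)
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    return HitTable(frame, {**raw.provenance, "deduplicated": "per_model" if per_model else "per_gene"})


# ---------------------------------------------------------------------------
# external per-target tabular results

def read_search_table(
    path,
    origin: str,
    sample_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> HitTable:
    """Read the standard whitespace-delimited per-target search table.

    Comment lines start with '#'. Data fields: target name, target
    accession, query name, query accession, full-sequence E-value,
    full-sequence score, ... Malformed rows are a hard error listing their
    line numbers.
    """
    if sample_of is None:
        lookup: Callable[[str], str] = _default_sample_of
    elif callable(sample_of):
        lookup = sample_of
    else:
        mapping = dict(sample_of)
        lookup = lambda g: mapping[g]  # noqa: E731

    rows, bad = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            try:
                if len(parts) < 6:
                    raise ValueError("fewer than 6 fields")
                target, _tacc, query, _qacc = parts[:4]
                evalue = float(parts[4])
                score = float(parts[5])
                if evalue <= 0:
                    raise ValueError("non-positive E-value")
            except ValueError as err:
                bad.append((lineno, str(err)))
                continue
            rows.append((target, lookup(target), query, score, evalue, origin))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad)
        raise ValueError(f"malformed search-table rows: {detail}")
    frame = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(frame, {"scorer": "external-tabular", "path": str(path)})


def write_search_table(table: HitTable, path) -> None:
    """Write hits in the per-target tabular dialect read_search_table parses."""
    with open(path, "w") as fh:
        fh.write("# target name\taccession\tquery name\taccession\tE-value\tscore\n")
        for row in table.frame.itertuples(index=False):
            fh.write(
                f"{row.gene_id} - {row.model_id} - {row.evalue:.6g} {row.bit_score:.6g}\n"
            )
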