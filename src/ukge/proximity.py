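"""Network-proximity validation of candidate drug-disease pairs.

A candidate pair is corroborated when the drug's target genes and the
disease's associated genes sit close together in a protein-interaction
embedding space.  Proximity is the median cosine similarity over all
cross-pairs of the two gene sets; its significance is judged against an
empirical null built by repeatedly drawing two same-sized sets of proteins
with replacement from the whole embedded proteome, with a Bonferroni
correction across the tested pairs.

The protein embedding (e.g. a 128-dimensional node embedding of a PPI
network) is consumed as a TSV matrix, not computed here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class ProteinEmbedding:
    """Protein ids with their embedding vectors (n x k)."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate protein ids")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("vector count does not match id count")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = [self.ids[i] for i in np.nonzero(norms == 0)[0][:3]]
            raise ValueError(f"zero-norm embedding vectors: {bad}")
        self.index = {p: i for i, p in enumerate(self.ids)}
        self.unit = self.vectors / norms[:, None]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProteinEmbedding":
        return cls(ids=[str(i) for i in df.index], vectors=df.to_numpy(dtype=float))

    def resolve(self, members: Iterable[str]) -> tuple[np.ndarray, int]:
        """Row indices of the members present in the embedding (multiplicity
        preserved) and the count of members dropped as missing."""
        idx, dropped = [], 0
        for m in members:
            if m in self.index:
                idx.append(self.index[m])
            else:
                dropped += 1
        return np.array(idx, dtype=np.intp), dropped


@dataclass
class ProximityResult:
    drug: str
    disease: str
    observed: float | None
    p_value: float | None
    n_perm: int
    significant: bool | None
    seed: int

    @property
    def testable(self) -> bool:
        return self.observed is not None


def median_cosine(
    embedding: ProteinEmbedding,
    set_a: Sequence[str],
    set_b: Sequence[str],
) -> float | None:
    """Median cosine similarity over all |A| x |B| protein pairs.

    Members absent from the embedding are dropped; if either set is empty
    after the intersection, returns None (the "no gene set" marker).
    Multiplicity is preserved, and the median of an even count is the
    midpoint of the two central values.
    """
    ia, _ = embedding.resolve(set_a)
    ib, _ = embedding.resolve(set_b)
    if ia.size == 0 or ib.size == 0:
        return None
    sims = embedding.unit[ia] @ embedding.unit[ib].T
    return float(np.median(sims))


def empirical_pvalue(
    embedding: ProteinEmbedding,
    set_a: Sequence[str],
    set_b: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    drug: str = "",
    disease: str = "",
) -> ProximityResult:
    """Permutation p-value of the observed median cosine similarity.

    Each replicate draws |A| and |B| proteins with replacement from all
    embedded proteins and recomputes the median cosine; the add-one
    estimator p = (1 + #{replicate >= observed}) / (1 + n_perm) keeps p
    strictly positive.  Deterministic given ``seed``.
    """
    ia, _ = embedding.resolve(set_a)
    ib, _ = embedding.resolve(set_b)
    if ia.size == 0 or ib.size == 0:
        return ProximityResult(
            drug=drug, disease=disease, observed=None, p_value=None,
            n_perm=n_perm, significant=None, seed=seed,
        )
    observed = float(np.median(embedding.unit[ia] @ embedding.unit[ib].T))
    rng = np.random.default_rng(seed)
    n = len(embedding.ids)
    a, b = ia.size, ib.size
    # Chunk replicates so the (chunk, a, b) similarity block stays small.
    chunk = max(1, int(2e6 // max(1, a * b)))
    exceed = 0
    use_gram = n * n <= 4_000_000
    G = embedding.unit @ embedding.unit.T if use_gram else None
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        ra = rng.integers(n, size=(m, a))
        rb = rng.integers(n, size=(m, b))
        if use_gram:
            block = G[ra[:, :, None], rb[:, None, :]]
            meds = np.median(block.reshape(m, a * b), axis=1)
        else:
            meds = np.empty(m)
            for j in range(m):
                meds[j] = np.median(embedding.unit[ra[j]] @ embedding.unit[rb[j]].T)
        exceed += int(np.sum(meds >= observed))
        done += m
    p = (1 + exceed) / (1 + n_perm)
    return ProximityResult(
        drug=drug, disease=disease, observed=observed, p_value=float(p),
        n_perm=n_perm, significant=None, seed=seed,
    )


def bonferroni_flag(
    results: list[ProximityResult], alpha: float = 0.05
) -> list[ProximityResult]:
    """Set each testable result's significance flag at the Bonferroni-adjusted
    threshold alpha / (number of testable pairs); untestable pairs stay None
    and are excluded from the denominator."""
    m = sum(1 for r in results if r.testable)
    out = []
    for r in results:
        if not r.testable:
            out.append(dataclasses.replace(r, significant=None))
        else:
            out.append(dataclasses.replace(r, significant=bool(r.p_value < alpha / m)))
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_protein_embedding(path: str | Path) -> ProteinEmbedding:
    """TSV: protein id in the first column, then k numeric columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ProteinEmbedding.from_frame(df)


def write_protein_embedding(embedding: ProteinEmbedding | pd.DataFrame, path: str | Path) -> None:
    if isinstance(embedding, ProteinEmbedding):
        df = pd.DataFrame(embedding.vectors, index=pd.Index(embedding.ids, name="id"))
    else:
        df = embedding
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (entity id, protein id) -> entity -> protein list."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if fields[0].lower() in {"entity", "drug", "disease", "id"}:
                    continue
            if len(fields) != 2:
                raise ValueError(f"expected 2 columns, got {fields!r}")
            sets.setdefault(fields[0], []).append(fields[1])
    return sets


def write_proximity_report(results: list[ProximityResult], path: str | Path,
                           header_lines: list[str] | None = None) -> None:
    """Report TSV: pair, observed median cosine, p-value, significance (N/A
    for pairs without gene sets)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("drug\tdisease\tobserved\tp_value\tsignificant\n")
        for r in results:
            if not r.testable:
                fh.write(f"{r.drug}\t{r.disease}\tN/A\tN/A\tN/A\n")
            else:
                sig = {True: "yes", False: "no", None: ""}[r.significant]
                fh.write(
                    f"{r.drug}\t{r.disease}\t{r.observed:.6g}\t{r.p_value:.6g}\t{sig}\n"
                )
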