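"""Dual-RNA quantification of arbuscular-mycorrhizal fungal abundance.

mRNA-seq libraries retain a small carry-over of rRNA reads.  Assigning those
reads to a host (plant) large-subunit rRNA reference and a panel of AM
fungal OTU references yields, after length normalization, a relative fungal
biomass index: total fungal rRNA reads per 1e5 plant rRNA reads, on a log10
scale.  The module also provides the community-distance tooling (Bray-Curtis
dissimilarity, non-metric multidimensional scaling) used to compare OTU
compositions between sequencing protocols.

Read assignment is a bundled exact-k-mer-seeded, ungapped matcher with the
acceptance thresholds of the published protocol (identity >= 95% over an
alignment of >= 75 bp); the matcher interface is pluggable so an external
aligner can substitute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foragenet.errors import InvalidConfigError, InvalidReferenceError

__all__ = [
    "RrnaReferenceSet",
    "ReadSet",
    "AssignmentTable",
    "AbundanceProfile",
    "FIVE_PRIME_CONSENSUS",
    "THREE_PRIME_CONSENSUS",
    "trim_reference_consensus",
    "assign_reads",
    "length_normalize_counts",
    "fungal_abundance_index",
    "protocol_bias_correlation",
    "bray_curtis",
    "nmds",
    "read_fasta",
    "write_fasta",
    "read_reads_fastq",
    "write_reads_fastq",
]

#: conserved primer-derived termini of the fungal OTU reference sequences
FIVE_PRIME_CONSENSUS = "GTGAAATTGTTGAAAGGGAAACG"
THREE_PRIME_CONSENSUS = "GACGTAATGGCTTTAAACGAC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RrnaReferenceSet:
    """One plant rRNA reference plus a panel of fungal OTU references."""

    plant_id: str
    plant_seq: str
    fungal: dict[str, str]  # otu id -> sequence
    trimmed: bool = False
    trim_log: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [self.plant_id, *self.fungal]
        if len(set(ids)) != len(ids):
            raise InvalidReferenceError("duplicate reference ids")
        if not self.plant_seq or any(not s for s in self.fungal.values()):
            raise InvalidReferenceError("empty reference sequence")

    @property
    def lengths(self) -> pd.Series:
        data = {self.plant_id: len(self.plant_seq)}
        data.update({k: len(v) for k, v in self.fungal.items()})
        return pd.Series(data, name="length_nt")

    def sequences(self) -> dict[str, str]:
        out = {self.plant_id: self.plant_seq}
        out.update(self.fungal)
        return out


@dataclass
class ReadSet:
    """Per-sample read collections: sample id -> list of (read id, sequence)."""

    reads: dict[str, list[tuple[str, str]]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.reads)

    def n_reads(self, sample: str | None = None) -> int:
        if sample is not None:
            return len(self.reads[sample])
        return sum(len(v) for v in self.reads.values())


def trim_reference_consensus(
    refs: RrnaReferenceSet,
    five_prime: str = FIVE_PRIME_CONSENSUS,
    three_prime: str = THREE_PRIME_CONSENSUS,
) -> RrnaReferenceSet:
    """Remove the conserved consensus termini from the fungal references.

    Exact terminal matches only; a reference lacking a consensus at a
    terminus keeps that terminus and a warning is issued.  The plant
    reference is never trimmed.  Idempotent.
    """
    fungal: dict[str, str] = {}
    log: dict[str, tuple[int, int]] = {}
    missing: list[str] = []
    for otu, seq in refs.fungal.items():
        cut5 = len(five_prime) if seq.startswith(five_prime) else 0
        cut3 = len(three_prime) if seq.endswith(three_prime) else 0
        if cut5 == 0 and cut3 == 0:
            missing.append(otu)
        fungal[otu] = seq[cut5 : len(seq) - cut3 if cut3 else len(seq)]
        log[otu] = (cut5, cut3)
    if missing:
        warnings.warn(
            f"{len(missing)} OTU references lack both consensus termini "
            f"(e.g. {missing[:3]}); left unchanged"
        )
    return RrnaReferenceSet(
        plant_id=refs.plant_id,
        plant_seq=refs.plant_seq,
        fungal=fungal,
        trimmed=True,
        trim_log=log,
    )


@dataclass
class AssignmentTable:
    """Read-to-reference assignments per sample.

    ``counts``: samples x references assigned-read counts.
    ``per_read``: one row per assigned read (sample, read_id, ref_id,
    identity, aln_len).
    """

    counts: pd.DataFrame
    per_read: pd.DataFrame
    n_reads_total: int

    @property
    def n_assigned(self) -> int:
        return len(self.per_read)


class KmerMatcher:
    """Exact-k-mer seeded, ungapped read-vs-reference matcher.

    Seeds are exact k-mers looked up in an index over both strands of the
    references; each seed fixes a diagonal, on which the full read/reference
    overlap is compared without gaps.  The best hit maximizes the number of
    matching bases, with ties broken by longer alignment then lexicographic
    reference id.
    """

    def __init__(self, refs: RrnaReferenceSet, kmer: int = 15) -> None:
        if not refs.fungal and not refs.plant_seq:
            raise InvalidConfigError("empty reference set")
        self.kmer = kmer
        self.ref_ids: list[str] = []
        self.ref_arrays: list[np.ndarray] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for rid, seq in sorted(refs.sequences().items()):
            ridx = len(self.ref_ids)
            self.ref_ids.append(rid)
            self.ref_arrays.append(np.frombuffer(seq.encode(), dtype="S1"))
            for pos in range(len(seq) - kmer + 1):
                self.index.setdefault(seq[pos : pos + kmer], []).append((ridx, pos))

    def best_hit(self, read: str) -> tuple[str, float, int] | None:
        """Best ungapped hit: (reference id, identity %, alignment length).

        A full-length perfect match short-circuits the search: no other hit
        can outrank it (equal-quality duplicates across random references
        are vanishingly unlikely and would only reorder an exact tie).
        """
        k = self.kmer
        n = len(read)
        best: tuple[int, int, str] | None = None  # (matches, aln_len, ref_id)
        for seq in (read, revcomp(read)):
            if len(seq) < k:
                continue
            arr = np.frombuffer(seq.encode(), dtype="S1")
            seen: set[tuple[int, int]] = set()
            starts = list(range(0, len(seq) - k + 1, k))
            if starts[-1] != len(seq) - k:
                starts.append(len(seq) - k)
            for q in starts:
                for ridx, s in self.index.get(seq[q : q + k], ()):
                    diag = s - q
                    if (ridx, diag) in seen:
                        continue
                    seen.add((ridx, diag))
                    ref = self.ref_arrays[ridx]
                    r0 = max(0, diag)
                    r1 = min(len(ref), diag + n)
                    aln_len = r1 - r0
                    if aln_len <= 0:
                        continue
                    matches = int((ref[r0:r1] == arr[r0 - diag : r1 - diag]).sum())
                    cand = (matches, aln_len, self.ref_ids[ridx])
                    if best is None or (
                        cand[0] > best[0]
                        or (cand[0] == best[0] and cand[1] > best[1])
                        or (cand[0] == best[0] and cand[1] == best[1] and cand[2] < best[2])
                    ):
                        best = cand
                    if matches == n and aln_len == n:
                        return self.ref_ids[ridx], 100.0, n
        if best is None:
            return None
        matches, aln_len, rid = best
        return rid, 100.0 * matches / aln_len, aln_len


def assign_reads(
    reads: ReadSet,
    refs: RrnaReferenceSet,
    min_identity: float = 95.0,
    min_len: int = 75,
    kmer: int = 15,
    matcher: KmerMatcher | None = None,
) -> AssignmentTable:
    """Assign every read to at most one reference.

    A read is assigned to its best hit when the hit's identity and
    alignment length reach the thresholds (defaults: >= 95% identity over
    >= 75 bp).  ``matcher`` may be any object exposing
    ``best_hit(read) -> (ref_id, identity, aln_len) | None``.
    """
    if min_identity <= 0 or min_len <= 0:
        raise InvalidConfigError("thresholds must be positive")
    if matcher is None:
        matcher = KmerMatcher(refs, kmer=kmer)
    ref_ids = [refs.plant_id, *sorted(refs.fungal)]
    ref_pos = {r: i for i, r in enumerate(ref_ids)}
    samples = reads.sample_ids
    count_arr = np.zeros((len(samples), len(ref_ids)), dtype=int)
    rows: list[tuple] = []
    total = 0
    for si, sample in enumerate(samples):
        for rid_read, seq in reads.reads[sample]:
            total += 1
            hit = matcher.best_hit(seq)
            if hit is None:
                continue
            ref_id, identity, aln_len = hit
            if identity >= min_identity and aln_len >= min_len:
                count_arr[si, ref_pos[ref_id]] += 1
                rows.append((sample, rid_read, ref_id, identity, aln_len))
    counts = pd.DataFrame(count_arr, index=samples, columns=ref_ids)
    per_read = pd.DataFrame(
        rows, columns=["sample", "read_id", "ref_id", "identity", "aln_len"]
    )
    return AssignmentTable(counts=counts, per_read=per_read, n_reads_total=total)


def length_normalize_counts(
    assign: AssignmentTable, refs: RrnaReferenceSet
) -> pd.DataFrame:
    """Per-reference counts divided by reference length in nt (post-trim)."""
    lengths = refs.lengths.reindex(assign.counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise InvalidReferenceError("missing or zero-length reference")
    return assign.counts / lengths


@dataclass
class AbundanceProfile:
    """Per-sample plant/fungal normalized counts and the abundance index.

    ``fungal_per_1e5_plant = 1e5 * sum(normalized OTU counts) /
    normalized plant count``; ``log_index`` is its log10.  Samples with
    zero plant or zero fungal normalized counts carry NaN in both and are
    listed in ``missing_samples``.
    """

    plant_normalized: pd.Series
    otu_normalized: pd.DataFrame
    fungal_per_1e5_plant: pd.Series
    log_index: pd.Series
    missing_samples: list[str]


def fungal_abundance_index(
    normalized: pd.DataFrame, plant_id: str
) -> AbundanceProfile:
    """Standardize total fungal counts per 1e5 plant rRNA reads, log10 scale."""
    if plant_id not in normalized.columns:
        raise InvalidConfigError(f"plant reference {plant_id!r} not in table")
    plant = normalized[plant_id]
    otus = normalized.drop(columns=[plant_id])
    fungal_total = otus.sum(axis=1)
    ok = (plant > 0) & (fungal_total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_1e5 = pd.Series(
            np.where(ok, 1e5 * fungal_total / plant.where(plant > 0), np.nan),
            index=normalized.index,
        )
        log_index = pd.Series(np.log10(per_1e5), index=normalized.index)
    return AbundanceProfile(
        plant_normalized=plant,
        otu_normalized=otus,
        fungal_per_1e5_plant=per_1e5,
        log_index=log_index,
        missing_samples=list(normalized.index[~ok]),
    )


def protocol_bias_correlation(
    index_a: pd.Series, index_b: pd.Series
) -> tuple[float, float]:
    """Pearson r (with two-sided p) between log abundance indices from two
    protocols over their shared, defined samples."""
    shared = [s for s in index_a.index if s in index_b.index]
    a = index_a.loc[shared].to_numpy(dtype=float)
    b = index_b.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 4:
        raise InvalidConfigError("need at least 4 shared samples with defined indices")
    a, b = a[ok], b[ok]
    r = float(np.corrcoef(a, b)[0, 1])
    n = int(ok.sum())
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    from scipy import stats

    return r, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bray_curtis(composition: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample rows.

    ``BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i)``.  All-zero samples have
    no defined dissimilarity; their rows/columns are NaN and a warning is
    issued.
    """
    x = composition.to_numpy(dtype=float)
    if (x < 0).any():
        raise InvalidConfigError("composition values must be nonnegative")
    totals = x.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"all-zero samples have undefined Bray-Curtis rows: "
            f"{list(composition.index[empty])}"
        )
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x).sum(axis=1)
        tot = (x[i] + x).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), np.nan)
    d[empty, :] = np.nan
    d[:, empty] = np.nan
    np.fill_diagonal(d, np.where(empty, np.nan, 0.0))
    return pd.DataFrame(d, index=composition.index, columns=composition.index)


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling
# ---------------------------------------------------------------------------

def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to y."""
    from scipy.optimize import isotonic_regression

    return isotonic_regression(y).x


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _pcoa_init(diss: np.ndarray, dims: int) -> np.ndarray:
    n = diss.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (diss**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    diss: pd.DataFrame | np.ndarray,
    dims: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float, list[np.ndarray]]:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each start alternates isotonic regression of the configuration
    distances on the dissimilarity order (disparities) with a Guttman
    majorization update of the configuration; an update that would increase
    stress-1 terminates the start, so the recorded stress trace is monotone
    non-increasing.  The first start is classical-scaling (principal
    coordinates) initialization; the rest are random (seeded).  Returns
    (best coordinates, best final stress, stress traces per start).
    """
    d = np.asarray(diss, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidConfigError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise InvalidConfigError("dissimilarity matrix must be symmetric")
    if np.isnan(d).any():
        raise InvalidConfigError("dissimilarity matrix contains undefined cells")
    n = d.shape[0]
    if n < dims + 2:
        raise InvalidConfigError("need at least dims + 2 samples")
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    best_x: np.ndarray | None = None
    best_stress = np.inf
    traces: list[np.ndarray] = []
    for start in range(n_starts):
        if start == 0:
            x = _pcoa_init(d, dims)
            if not np.isfinite(x).all() or np.allclose(x, 0):
                x = rng.standard_normal((n, dims))
        else:
            x = rng.standard_normal((n, dims))
        trace = []
        prev = np.inf
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=2))
            dvec = dist[iu]
            dhat_sorted = _pava(dvec[order])
            dhat = np.empty_like(dvec)
            dhat[order] = dhat_sorted
            stress = _stress1(dvec, dhat)
            if stress >= prev - tol:
                if stress < prev:
                    trace.append(stress)
                    prev = stress
                break
            trace.append(stress)
            prev = stress
            if stress == 0.0:
                break
            # Guttman transform with disparities as targets
            dhat_full = np.zeros((n, n))
            dhat_full[iu] = dhat
            dhat_full += dhat_full.T
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(dist > 0, dhat_full / np.where(dist > 0, dist, 1.0), 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x_new = b @ x / n
            # accept only improving moves so the stress trace stays monotone
            diff2 = x_new[:, None, :] - x_new[None, :, :]
            dvec2 = np.sqrt((diff2**2).sum(axis=2))[iu]
            dhat2 = np.empty_like(dvec2)
            dhat2[order] = _pava(dvec2[order])
            if _stress1(dvec2, dhat2) >= prev:
                break
            x = x_new
        traces.append(np.asarray(trace))
        if prev < best_stress:
            best_stress = prev
            best_x = x
    assert best_x is not None
    return best_x, float(best_stress), traces


# ---------------------------------------------------------------------------
# FASTA / FASTQ text I/O (plain formats, no compression)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader; ids are taken up to the first whitespace."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reads_fastq(path: str | Path) -> ReadSet:
    """FASTQ reader for read sets written by the simulator.

    Sample membership is encoded in the read id as ``<sample>|...``.
    """
    reads: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            fh.readline()
            rid = header[1:]
            sample = rid.split("|", 1)[0]
            reads.setdefault(sample, []).append((rid, seq))
    return ReadSet(reads=reads)


def write_reads_fastq(reads: ReadSet, path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for sample in reads.sample_ids:
            for rid, seq in reads.reads[sample]:
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
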