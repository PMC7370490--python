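"""Synthetic metagenome simulator with planted integron cassette arrays.

Contigs of background sequence carry planted cassette arrays that follow
the attC grammar: each cassette is an ORF followed by an attC site whose
R''/R' and L''/L' motif pairs are generated exactly complementary (with
the single extra-helical nucleotide in L'') and then mutated at a
configurable per-position rate.  Consecutive attC gaps stay within the
proximity limit by construction, arrays carry 2-8 cassettes, ORF lengths
follow a log-normal centred on a 402 nt median, and every planted element
is recorded in a truth table for evaluation.

Negative controls are produced by a dinucleotide-preserving Euler-path
shuffle, which destroys planted sites while keeping length and
dinucleotide composition of each contig exactly.

Planted truth is kept unambiguous: after building a contig the simulator
checks, with the package's own ORF finder and association rules against
the planted attC coordinates, that exactly the planted genes would be
associated; contigs where background sequence happens to create a
competing associable reading frame are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .assembly import CassetteArray, associate_orfs
from .model import (
    BASES, CONSENSUS_R1, IUPAC, L2_BULGE_INDEX, LEN_R2, LOOP_SUPPORT,
    MOTIF_TOTAL, SITE_LEN_BOUNDS, SPACER_SUPPORT, reverse_complement,
)
from .orfs import OrfRecord, find_orfs
from .scan import AttcHit

STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimParams:
    """Study conditions for the synthetic metagenome.

    Defaults emulate the target regime: arrays of 2-8 cassettes, ORF
    lengths log-normal with median ~402 nt, attC sites drawn from the
    consensus grammar with 5% per-position motif mutations, balanced
    strands and an i.i.d. background of 50% G+C.
    """

    seed: int = 0
    n_contigs: int = 100
    n_arrays: int = 100
    contig_len: tuple[int, int] = (12_000, 18_000)
    background_gc: float = 0.5
    cassettes_per_array: tuple[int, int] = (2, 8)
    motif_mut_rate: float = 0.05
    orf_len_median: float = 402.0
    orf_len_sigma: float = 0.6
    orf_len_bounds: tuple[int, int] = (102, 999)
    orf_gap: tuple[int, int] = (5, 60)          # ORF end -> attC start, nt
    intercassette_gap: tuple[int, int] = (30, 200)
    strand_p: float = 0.5                       # probability of + strand
    verify_truth: bool = True
    max_retries: int = 100

    def check(self) -> None:
        for name in ("background_gc", "motif_mut_rate", "strand_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cassettes_per_array[0] < 2:
            raise ValueError("cassettes_per_array support must start at >= 2")
        if self.n_contigs < 1 or self.n_arrays < 0:
            raise ValueError("n_contigs must be >= 1 and n_arrays >= 0")

    @classmethod
    def from_yaml(cls, text: str) -> "SimParams":
        data = yaml.safe_load(text) or {}
        params = cls(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in data.items()})
        params.check()
        return params

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


@dataclass
class TruthAttc:
    contig_id: str
    strand: str
    start: int
    end: int
    segment_lengths: tuple[int, ...]
    array_id: int
    ordinal: int


@dataclass
class TruthOrf:
    contig_id: str
    strand: str
    start: int
    end: int
    array_id: int
    ordinal: int


@dataclass
class SimTruth:
    """Coordinates of every planted element, for evaluation."""

    attcs: list[TruthAttc] = field(default_factory=list)
    orfs: list[TruthOrf] = field(default_factory=list)

    def n_arrays(self) -> int:
        return len({(a.contig_id, a.array_id) for a in self.attcs})


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    idx = rng.choice(4, size=n, p=[at, g, g, at])
    return "".join("AGCT"[i] for i in idx)


def _realize_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(c if c in BASES else IUPAC[c][rng.integers(len(IUPAC[c]))]
                   for c in consensus)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, c in enumerate(out):
        if rng.random() < rate:
            others = [b for b in BASES if b != c]
            out[i] = others[rng.integers(3)]
    return "".join(out)


def make_attc_site(rng: np.random.Generator, gc: float,
                   mut_rate: float) -> tuple[str, tuple[int, ...]]:
    """One attC site in scanned-strand orientation, plus its segment lengths.

    Motif pairs are generated exactly complementary (L'' gains one bulged
    nucleotide) before per-position mutation at ``mut_rate``.
    """
    s_lo, s_hi = SPACER_SUPPORT
    l_lo, l_hi = LOOP_SUPPORT
    while True:
        d1 = int(rng.integers(s_lo, s_hi + 1))
        d2 = int(rng.integers(s_lo, s_hi + 1))
        loop = int(rng.integers(l_lo, l_hi + 1))
        total = MOTIF_TOTAL + d1 + loop + d2
        if SITE_LEN_BOUNDS[0] <= total <= SITE_LEN_BOUNDS[1]:
            break
    r1 = _realize_consensus(rng, CONSENSUS_R1)
    r2 = reverse_complement(r1)
    l1 = _realize_consensus(rng, CONSENSUS_R1)
    core = reverse_complement(l1)
    bulge = "AGCT"[rng.integers(4)]
    l2 = core[:L2_BULGE_INDEX] + bulge + core[L2_BULGE_INDEX:]
    site = (_mutate(rng, r2, mut_rate) + _random_seq(rng, d1, gc)
            + _mutate(rng, l2, mut_rate) + _random_seq(rng, loop, gc)
            + _mutate(rng, l1, mut_rate) + _random_seq(rng, d2, gc)
            + _mutate(rng, r1, mut_rate))
    lengths = (LEN_R2, d1, 8, loop, 7, d2, 7)
    return site, lengths


def make_orf(rng: np.random.Generator, params: SimParams) -> str:
    """A clean complete ORF: ATG + stop-free codons + stop codon.

    So that the planted gene is the *only* associable call in its locus,
    the body is seeded with periodic dicodon motifs that place stop codons
    in both shifted reading frames of the same strand (every 16 codons,
    well under the 25-codon minimum gene length) while staying stop-free
    in frame.  This emulates the single-gene-per-locus behaviour of a
    coding-statistics gene finder without biasing frame-0 content.
    """
    lo, hi = params.orf_len_bounds
    n = float(rng.lognormal(mean=np.log(params.orf_len_median),
                            sigma=params.orf_len_sigma))
    n = int(min(max(n, lo), hi)) // 3 * 3
    body_codons = n // 3 - 2
    body = _random_seq(rng, 3 * body_codons, params.background_gc)
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    while True:
        bad = [i for i, c in enumerate(codons) if c in STOPS]
        if not bad:
            break
        for i in bad:
            codons[i] = _random_seq(rng, 3, params.background_gc)
    # alt-frame stop seeds: type A puts TAA in frame +1, type B in frame +2
    first_base = "ACGT"
    for j, k in enumerate(range(1, body_codons - 1, 8)):
        if j % 2 == 0:
            codons[k] = first_base[rng.integers(4)] + "TA"   # xTA, never a stop
            codons[k + 1] = "A" + codons[k + 1][1:]          # A.. never a stop
        else:
            codons[k] = codons[k][:2] + "T"                  # ..T never a stop
            codons[k + 1] = "AA" + codons[k + 1][2]          # AA. never a stop
    stop = STOPS[rng.integers(3)]
    return "ATG" + "".join(codons) + stop


def _build_array(rng: np.random.Generator, params: SimParams):
    """One cassette array on the + strand of its own local sequence.

    Returns (sequence, attc local intervals+lengths, orf local intervals).
    """
    n_cass = int(rng.integers(params.cassettes_per_array[0],
                              params.cassettes_per_array[1] + 1))
    parts: list[str] = []
    attcs = []
    orfs = []
    pos = 0
    for ordinal in range(1, n_cass + 1):
        if ordinal > 1:
            gap = int(rng.integers(*params.intercassette_gap))
            parts.append(_random_seq(rng, gap, params.background_gc))
            pos += gap
        # in-frame stop just upstream of the gene start pins the called
        # ORF's 5' end to the planted ATG
        parts.append("TAA")
        pos += 3
        orf = make_orf(rng, params)
        parts.append(orf)
        orfs.append((pos, pos + len(orf), ordinal))
        pos += len(orf)
        ogap = int(rng.integers(*params.orf_gap))
        parts.append(_random_seq(rng, ogap, params.background_gc))
        pos += ogap
        site, lengths = make_attc_site(rng, params.background_gc,
                                       params.motif_mut_rate)
        parts.append(site)
        attcs.append((pos, pos + len(site), lengths, ordinal))
        pos += len(site)
    return "".join(parts), attcs, orfs


#: minimum background separation between arrays on one contig, chosen above
#: the proximity limit so distinct arrays can never chain together
ARRAY_SEPARATION = 4200


def _build_contig(rng: np.random.Generator, params: SimParams, contig_id: str,
                  n_arrays: int, contig_len: int):
    arrays = [_build_array(rng, params) for _ in range(n_arrays)]
    total_array = sum(len(a[0]) for a in arrays)
    n_gaps = n_arrays + 1
    min_bg = ARRAY_SEPARATION * max(0, n_arrays - 1) + 2 * 100
    if total_array + min_bg > contig_len:
        raise ValueError(
            f"{contig_id}: contig of {contig_len} nt too short for {n_arrays} "
            f"array(s) totalling {total_array} nt plus separation")
    spare = contig_len - total_array - min_bg
    cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1)) if n_gaps > 1 else []
    shares = np.diff(np.concatenate([[0], cuts, [spare]])) if n_gaps > 1 else [spare]
    gaps = [int(s) + (100 if i in (0, n_gaps - 1) else ARRAY_SEPARATION)
            for i, s in enumerate(shares)]
    if n_arrays == 0:
        return _random_seq(rng, contig_len, params.background_gc), [], []
    parts = []
    attcs = []
    orfs = []
    pos = 0
    for i, (aseq, a_attcs, a_orfs) in enumerate(arrays):
        parts.append(_random_seq(rng, gaps[i], params.background_gc))
        pos += gaps[i]
        strand = "+" if rng.random() < params.strand_p else "-"
        alen = len(aseq)
        if strand == "+":
            parts.append(aseq)
            for s, e, lengths, ordinal in a_attcs:
                attcs.append((pos + s, pos + e, strand, lengths, i, ordinal))
            for s, e, ordinal in a_orfs:
                orfs.append((pos + s, pos + e, strand, i, ordinal))
        else:
            parts.append(reverse_complement(aseq))
            for s, e, lengths, ordinal in a_attcs:
                attcs.append((pos + alen - e, pos + alen - s, strand, lengths,
                              i, ordinal))
            for s, e, ordinal in a_orfs:
                orfs.append((pos + alen - e, pos + alen - s, strand, i, ordinal))
        pos += alen
    parts.append(_random_seq(rng, gaps[-1], params.background_gc))
    return "".join(parts), attcs, orfs


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _orf_truth(contig_id: str, seq: str, attcs, planted_orfs):
    """ORF truth for one contig: everything the association rules yield
    when fed the *planted* attC coordinates.

    The truth table must describe what a pipeline with a perfect attC
    detector reports.  Besides the planted genes this includes background
    ORFs that legitimately satisfy the association rules (e.g. a complete
    ORF ending within the first-cassette window); a cassette may therefore
    carry more than one truth ORF.  Returns ``None`` when a planted gene
    itself fails to be recovered (so the contig can be resampled).
    """
    by_array: dict[tuple[int, str], list[AttcHit]] = {}
    hit_array: dict[int, int] = {}
    for s, e, strand, lengths, array_id, _ in attcs:
        hit = AttcHit(contig_id=contig_id, strand=strand, start=s, end=e,
                      segment_lengths=tuple(lengths), hmm_score=1.0,
                      structure_score=1.0)
        by_array.setdefault((array_id, strand), []).append(hit)
        hit_array[id(hit)] = array_id
    arrays = [CassetteArray(contig_id, strand, sorted(hits, key=lambda h: h.start))
              for (array_id, strand), hits in sorted(by_array.items())]
    found = find_orfs((contig_id, seq))
    cassettes = associate_orfs(arrays, found,
                               contig_lengths={contig_id: len(seq)})
    assigned = [(o, hit_array[id(c.attc)], c.ordinal)
                for c in cassettes for o in c.orfs]
    for s, e, strand, _, _ in planted_orfs:
        if not any(o.strand == strand
                   and _reciprocal_overlap((s, e), (o.start, o.end)) >= 0.5
                   for o, _, _ in assigned):
            return None
    return [TruthOrf(contig_id, o.strand, o.start, o.end, array_id, ordinal)
            for o, array_id, ordinal in assigned]


def simulate_metagenome(params: SimParams) -> tuple[list[tuple[str, str]], SimTruth]:
    """Generate contigs with planted cassette arrays and their truth table.

    Deterministic given ``params.seed``.  Returns ``(records, truth)``
    where records are (contig_id, sequence) pairs.  With
    ``verify_truth`` (the default), the ORF truth is derived by applying
    the association rules to the planted attC coordinates, and a contig is
    resampled in the rare case where a planted gene is not itself
    recoverable; with ``verify_truth=False`` the truth lists only the
    planted elements (faster; used e.g. for negative-control material that
    is subsequently shuffled).
    """
    params.check()
    per_contig = [params.n_arrays // params.n_contigs] * params.n_contigs
    for i in range(params.n_arrays % params.n_contigs):
        per_contig[i] += 1
    records: list[tuple[str, str]] = []
    truth = SimTruth()
    for ci in range(params.n_contigs):
        contig_id = f"contig_{ci + 1:05d}"
        lo, hi = params.contig_len
        rng0 = np.random.default_rng([params.seed, ci, 0])
        contig_len = int(rng0.integers(lo, hi + 1))
        orf_truth = None
        for attempt in range(params.max_retries):
            rng = np.random.default_rng([params.seed, ci, attempt + 1])
            seq, attcs, orfs = _build_contig(rng, params, contig_id,
                                             per_contig[ci], contig_len)
            if not params.verify_truth:
                orf_truth = [TruthOrf(contig_id, strand, s, e, array_id, ordinal)
                             for s, e, strand, array_id, ordinal in orfs]
                break
            orf_truth = _orf_truth(contig_id, seq, attcs, orfs)
            if orf_truth is not None:
                break
        else:
            raise RuntimeError(
                f"{contig_id}: planted genes not recoverable in "
                f"{params.max_retries} attempts")
        records.append((contig_id, seq))
        for s, e, strand, lengths, array_id, ordinal in attcs:
            truth.attcs.append(TruthAttc(contig_id, strand, s, e,
                                         tuple(lengths), array_id, ordinal))
        truth.orfs.extend(orf_truth)
    return records, truth


def make_training_sites(n: int = 231, seed: int = 0, gc: float = 0.5,
                        mut_rate: float = 0.05):
    """Annotated attC sites drawn from the simulator's site population.

    Mirrors a curated training set at desk scale: ``n`` sites with their
    true segment boundaries, sampled from the same grammar (and the same
    per-position motif divergence) as the planted sites.
    """
    from .model import TrainingSite
    rng = np.random.default_rng([seed, 231])
    out = []
    for i in range(n):
        site, lengths = make_attc_site(rng, gc, mut_rate)
        out.append(TrainingSite(sequence=site, boundaries=lengths,
                                site_id=f"train_{i + 1:03d}"))
    return out


def reference_model(seed: int = 0, n_sites: int = 231, gc: float = 0.5,
                    mut_rate: float = 0.05, pseudocount: float = 1.0):
    """The pipeline's working model: a gHMM trained on simulated sites."""
    from .model import train_model
    return train_model(make_training_sites(n_sites, seed, gc, mut_rate),
                       pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Euler-path method)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving length and the exact dinucleotide count table.

    Altschul-Erickson construction: the sequence is an Euler path in the
    multigraph whose edges are its dinucleotides.  A random arborescence
    toward the final symbol fixes each vertex's last outgoing edge; the
    remaining edges are permuted and the path is re-walked.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    verts = sorted(set(seq))
    vi = {c: i for i, c in enumerate(verts)}
    nv = len(verts)
    succ: list[list[str]] = [[] for _ in range(nv)]
    for a, b in zip(seq, seq[1:]):
        succ[vi[a]].append(b)
    last_v = vi[seq[-1]]
    # choose last edges forming an arborescence into the final vertex
    while True:
        last_edge = [None] * nv
        for v in range(nv):
            if v != last_v and succ[v]:
                last_edge[v] = succ[v][rng.integers(len(succ[v]))]
        ok = True
        for v in range(nv):
            if v == last_v or not succ[v]:
                continue
            seen = set()
            cur = v
            while cur != last_v:
                if cur in seen or last_edge[cur] is None:
                    ok = False
                    break
                seen.add(cur)
                cur = vi[last_edge[cur]]
            if not ok:
                break
        if ok:
            break
    lists: list[list[str]] = []
    for v in range(nv):
        edges = list(succ[v])
        if last_edge[v] is not None:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        shuffled = [edges[i] for i in perm]
        if last_edge[v] is not None:
            shuffled.append(last_edge[v])
        lists.append(shuffled)
    ptr = [0] * nv
    out = [seq[0]]
    cur = vi[seq[0]]
    for _ in range(len(seq) - 1):
        nxt = lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = vi[nxt]
    return "".join(out)


def shuffle_negative(contigs: list[tuple[str, str]], seed: int) -> list[tuple[str, str]]:
    """Dinucleotide-preserving shuffle of each contig; deterministic by seed."""
    out = []
    for i, (cid, seq) in enumerate(contigs):
        rng = np.random.default_rng([seed, i])
        out.append((f"{cid}_shuffled", dinucleotide_shuffle(seq, rng)))
    return out


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    attc_total: int
    attc_detected: int
    attc_false_positives: int
    orf_total: int
    orf_detected: int
    orf_false_positives: int
    attc_boundary_mean: float

    @property
    def attc_sensitivity(self) -> float:
        return self.attc_detected / self.attc_total if self.attc_total else 0.0

    @property
    def orf_sensitivity(self) -> float:
        return self.orf_detected / self.orf_total if self.orf_total else 0.0


def evaluate(pred_attcs: list[AttcHit], pred_orfs: list[OrfRecord],
             truth: SimTruth, boundary_tol: int | None = 10) -> EvalResult:
    """Compare predictions with planted truth.

    A truth attC counts as detected when a prediction on the same contig
    and strand overlaps it reciprocally by >= 50% and, if ``boundary_tol``
    is set, with both boundaries within that many nt.  A prediction is a
    false positive when it reciprocally matches no truth element.  ORFs use
    the reciprocal-overlap rule alone, since legitimate calls may extend a
    planted gene's start upstream.
    """
    def keyed(elems, fn):
        d: dict[tuple[str, str], list] = {}
        for e in elems:
            d.setdefault(fn(e), []).append(e)
        return d

    pa = keyed(pred_attcs, lambda h: (h.contig_id, h.strand))
    attc_detected = 0
    boundary_errors = []
    for t in truth.attcs:
        best = None
        for p in pa.get((t.contig_id, t.strand), []):
            if _reciprocal_overlap((t.start, t.end), (p.start, p.end)) >= 0.5:
                err = max(abs(p.start - t.start), abs(p.end - t.end))
                if best is None or err < best:
                    best = err
        if best is not None and (boundary_tol is None or best <= boundary_tol):
            attc_detected += 1
            boundary_errors.append(best)
    ta = keyed(truth.attcs, lambda t: (t.contig_id, t.strand))
    attc_fp = sum(
        1 for p in pred_attcs
        if not any(_reciprocal_overlap((t.start, t.end), (p.start, p.end)) >= 0.5
                   for t in ta.get((p.contig_id, p.strand), [])))
    po = keyed(pred_orfs, lambda o: (o.contig_id, o.strand))
    orf_detected = sum(
        1 for t in truth.orfs
        if any(_reciprocal_overlap((t.start, t.end), (p.start, p.end)) >= 0.5
               for p in po.get((t.contig_id, t.strand), [])))
    to = keyed(truth.orfs, lambda t: (t.contig_id, t.strand))
    orf_fp = sum(
        1 for p in pred_orfs
        if not any(_reciprocal_overlap((t.start, t.end), (p.start, p.end)) >= 0.5
                   for t in to.get((p.contig_id, p.strand), [])))
    return EvalResult(
        attc_total=len(truth.attcs), attc_detected=attc_detected,
        attc_false_positives=attc_fp,
        orf_total=len(truth.orfs), orf_detected=orf_detected,
        orf_false_positives=orf_fp,
        attc_boundary_mean=float(np.mean(boundary_errors)) if boundary_errors
        else float("nan"))
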