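"""Probabilistic model of the attC recombination site.

An attC site is an imperfect palindrome of 55-141 nt whose bottom strand
folds into a hairpin through two pairs of complementary motifs, R''/R' and
L''/L'.  Along the scanned (hairpin) strand the site reads

    R'' - spacer1 - L'' - loop - L' - spacer2 - R'

with fixed-length motifs (R''=7, L''=8, L'=7, R'=7 nt; L'' carries one
extra-helical nucleotide), spacers of 1-10 nt and a central loop of
14-102 nt.  R' and R'' are the most conserved parts, with general motifs
RYYYAAC and GTTRRRY respectively.

:class:`AttcModel` holds per-position nucleotide probability tables (PWMs)
for the four motifs, explicit duration distributions for the variable
regions, and a 0-order background — the emission side of a seven-state
generalized hidden Markov model with duration modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Fixed motif lengths along the scanned strand.
LEN_R2 = 7   # R''
LEN_L2 = 8   # L''  (one extra-helical nucleotide vs L')
LEN_L1 = 7   # L'
LEN_R1 = 7   # R'
MOTIF_TOTAL = LEN_R2 + LEN_L2 + LEN_L1 + LEN_R1

SPACER_SUPPORT = (1, 10)
LOOP_SUPPORT = (14, 102)
SITE_LEN_BOUNDS = (55, 141)

CONSENSUS_R1 = "RYYYAAC"
CONSENSUS_R2 = "GTTRRRY"
#: Index of the default extra-helical (bulged) column in the L'' PWM.
L2_BULGE_INDEX = 3


def _consensus_column(letter: str, weight: float = 0.45) -> np.ndarray:
    """PWM column for one IUPAC consensus letter.

    Each base consistent with the letter receives ``weight``; the leftover
    probability is spread equally over the inconsistent bases.  An 'N'
    yields the uniform column.
    """
    consistent = IUPAC[letter]
    col = np.empty(4)
    if len(consistent) == 4:
        col[:] = 0.25
        return col
    rest = (1.0 - weight * len(consistent)) / (4 - len(consistent))
    for b, i in BASE_INDEX.items():
        col[i] = weight if b in consistent else rest
    return col


def consensus_pwm(consensus: str, weight: float = 0.45) -> np.ndarray:
    """Stack of consensus columns, shape (len(consensus), 4)."""
    return np.stack([_consensus_column(c, weight) for c in consensus])


def _uniform_pmf(support: tuple[int, int]) -> np.ndarray:
    lo, hi = support
    return np.full(hi - lo + 1, 1.0 / (hi - lo + 1))


def reverse_complement(seq: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
    }
    return "".join(comp[c] for c in reversed(seq.upper()))


@dataclass
class AttcModel:
    """Emission and duration parameters of the seven-state attC gHMM.

    PWMs are (length, 4) arrays over A,C,G,T; duration pmfs are dense over
    their declared integer support; ``region_composition`` is the 0-order
    nucleotide distribution used inside spacers and the loop and
    ``background`` the null distribution the log-odds are taken against.
    """

    pwm_R2: np.ndarray
    pwm_L2: np.ndarray
    pwm_L1: np.ndarray
    pwm_R1: np.ndarray
    dur_spacer1: np.ndarray
    dur_spacer2: np.ndarray
    dur_loop: np.ndarray
    region_composition: np.ndarray
    background: np.ndarray
    spacer_support: tuple[int, int] = SPACER_SUPPORT
    loop_support: tuple[int, int] = LOOP_SUPPORT
    site_len_bounds: tuple[int, int] = SITE_LEN_BOUNDS

    def __post_init__(self) -> None:
        for name in ("pwm_R2", "pwm_L2", "pwm_L1", "pwm_R1",
                     "dur_spacer1", "dur_spacer2", "dur_loop",
                     "region_composition", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.spacer_support = tuple(self.spacer_support)
        self.loop_support = tuple(self.loop_support)
        self.site_len_bounds = tuple(self.site_len_bounds)

    # -- validation ----------------------------------------------------

    def validate(self, strict_positive: bool = True) -> None:
        """Check the model invariants; raise ValueError on violation."""
        expect = {
            "pwm_R2": LEN_R2, "pwm_L2": LEN_L2,
            "pwm_L1": LEN_L1, "pwm_R1": LEN_R1,
        }
        for name, length in expect.items():
            pwm = getattr(self, name)
            if pwm.shape != (length, 4):
                raise ValueError(f"{name} must have shape ({length}, 4), got {pwm.shape}")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} columns must each sum to 1")
            if strict_positive and not (pwm > 0).all():
                raise ValueError(f"{name} entries must be strictly positive")
        for name, support in (("dur_spacer1", self.spacer_support),
                              ("dur_spacer2", self.spacer_support),
                              ("dur_loop", self.loop_support)):
            pmf = getattr(self, name)
            n = support[1] - support[0] + 1
            if pmf.shape != (n,):
                raise ValueError(f"{name} must have {n} entries for support {support}")
            if not np.isclose(pmf.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1 over its support")
            if (pmf < 0).any():
                raise ValueError(f"{name} entries must be non-negative")
        for name in ("region_composition", "background"):
            dist = getattr(self, name)
            if dist.shape != (4,) or not np.isclose(dist.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must be a length-4 distribution")
        if self.site_len_bounds[0] < MOTIF_TOTAL:
            raise ValueError(
                f"site_len_bounds minimum must be >= {MOTIF_TOTAL} (sum of motif lengths)")

    # -- convenience ---------------------------------------------------

    @property
    def min_site_len(self) -> int:
        return self.site_len_bounds[0]

    @property
    def max_site_len(self) -> int:
        return self.site_len_bounds[1]

    def duration_logpmf(self, which: str) -> np.ndarray:
        """log pmf over the declared support (``-inf`` where mass is 0)."""
        pmf = {"spacer1": self.dur_spacer1, "spacer2": self.dur_spacer2,
               "loop": self.dur_loop}[which]
        with np.errstate(divide="ignore"):
            return np.log(pmf)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        data = {
            "pwm_R2": self.pwm_R2.tolist(), "pwm_L2": self.pwm_L2.tolist(),
            "pwm_L1": self.pwm_L1.tolist(), "pwm_R1": self.pwm_R1.tolist(),
            "dur_spacer1": self.dur_spacer1.tolist(),
            "dur_spacer2": self.dur_spacer2.tolist(),
            "dur_loop": self.dur_loop.tolist(),
            "region_composition": self.region_composition.tolist(),
            "background": self.background.tolist(),
            "spacer_support": list(self.spacer_support),
            "loop_support": list(self.loop_support),
            "site_len_bounds": list(self.site_len_bounds),
        }
        return json.dumps(data, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AttcModel":
        data = json.loads(text)
        model = cls(**data)
        model.validate(strict_positive=False)
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "AttcModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_default_model() -> AttcModel:
    """Consensus-derived default model.

    Motif PWMs place 0.45 on each base consistent with the IUPAC consensus
    (R' = RYYYAAC, R'' = GTTRRRY; the L boxes default to the complementary
    pairing of the R boxes, with one uninformative extra-helical column in
    L''), durations are uniform over their supports and the background is
    uniform.
    """
    pwm_R1 = consensus_pwm(CONSENSUS_R1)
    pwm_R2 = consensus_pwm(CONSENSUS_R2)
    # L' mirrors the R' consensus; L'' is its reverse complement with an
    # uninformative bulged column inserted.
    consensus_L1 = CONSENSUS_R1
    consensus_L2_core = reverse_complement(consensus_L1)  # == GTTRRRY
    consensus_L2 = (consensus_L2_core[:L2_BULGE_INDEX] + "N"
                    + consensus_L2_core[L2_BULGE_INDEX:])
    model = AttcModel(
        pwm_R2=pwm_R2,
        pwm_L2=consensus_pwm(consensus_L2),
        pwm_L1=consensus_pwm(consensus_L1),
        pwm_R1=pwm_R1,
        dur_spacer1=_uniform_pmf(SPACER_SUPPORT),
        dur_spacer2=_uniform_pmf(SPACER_SUPPORT),
        dur_loop=_uniform_pmf(LOOP_SUPPORT),
        region_composition=np.full(4, 0.25),
        background=np.full(4, 0.25),
    )
    model.validate()
    return model


@dataclass
class TrainingSite:
    """One annotated attC site in hairpin (scanned-strand) orientation.

    ``boundaries`` are the seven segment lengths in grammar order
    (R'', spacer1, L'', loop, L', spacer2, R').
    """

    sequence: str
    boundaries: tuple[int, int, int, int, int, int, int]
    site_id: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.boundaries = tuple(int(b) for b in self.boundaries)

    def check(self) -> None:
        r2, s1, l2, loop, l1, s2, r1 = self.boundaries
        if (r2, l2, l1, r1) != (LEN_R2, LEN_L2, LEN_L1, LEN_R1):
            raise ValueError(
                f"site {self.site_id!r}: motif lengths {(r2, l2, l1, r1)} must be "
                f"{(LEN_R2, LEN_L2, LEN_L1, LEN_R1)}")
        for name, v in (("spacer1", s1), ("spacer2", s2)):
            if not SPACER_SUPPORT[0] <= v <= SPACER_SUPPORT[1]:
                raise ValueError(
                    f"site {self.site_id!r}: {name} length {v} outside "
                    f"support {SPACER_SUPPORT}")
        if not LOOP_SUPPORT[0] <= loop <= LOOP_SUPPORT[1]:
            raise ValueError(
                f"site {self.site_id!r}: loop length {loop} outside support {LOOP_SUPPORT}")
        if sum(self.boundaries) != len(self.sequence):
            raise ValueError(
                f"site {self.site_id!r}: segment lengths sum to {sum(self.boundaries)} "
                f"but sequence has {len(self.sequence)} nt")

    def segments(self) -> dict[str, str]:
        out = {}
        pos = 0
        for name, length in zip(
                ("R2", "spacer1", "L2", "loop", "L1", "spacer2", "R1"),
                self.boundaries):
            out[name] = self.sequence[pos:pos + length]
            pos += length
        return out


def _count_pwm(seqs: list[str], length: int, alpha: float) -> np.ndarray:
    counts = np.zeros((length, 4))
    for s in seqs:
        for i, c in enumerate(s):
            bases = IUPAC.get(c, "")
            if len(bases) == 1:
                counts[i, BASE_INDEX[bases]] += 1.0
            elif bases:
                # fractional count for ambiguity codes
                for b in bases:
                    counts[i, BASE_INDEX[b]] += 1.0 / len(bases)
    n = len(seqs)
    return (counts + alpha) / (n + 4.0 * alpha)


def _count_pmf(values: list[int], support: tuple[int, int], alpha: float) -> np.ndarray:
    lo, hi = support
    counts = np.zeros(hi - lo + 1)
    for v in values:
        counts[v - lo] += 1.0
    n = len(values)
    return (counts + alpha) / (n + (hi - lo + 1) * alpha)


def train_model(sites: list[TrainingSite], pseudocount: float = 1.0) -> AttcModel:
    """Maximum-likelihood estimation with additive smoothing.

    PWM entries are (count + a)/(n + 4a) per position, duration pmfs
    (count + a)/(n + |support| * a), and the variable-region composition is
    pooled over all spacer and loop residues.  ``pseudocount`` may be 0 for
    plain empirical frequencies.
    """
    if not sites:
        raise ValueError("training set is empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for site in sites:
        site.check()
    segs = [s.segments() for s in sites]
    alpha = float(pseudocount)
    pwm_R2 = _count_pwm([g["R2"] for g in segs], LEN_R2, alpha)
    pwm_L2 = _count_pwm([g["L2"] for g in segs], LEN_L2, alpha)
    pwm_L1 = _count_pwm([g["L1"] for g in segs], LEN_L1, alpha)
    pwm_R1 = _count_pwm([g["R1"] for g in segs], LEN_R1, alpha)
    dur_s1 = _count_pmf([s.boundaries[1] for s in sites], SPACER_SUPPORT, alpha)
    dur_loop = _count_pmf([s.boundaries[3] for s in sites], LOOP_SUPPORT, alpha)
    dur_s2 = _count_pmf([s.boundaries[5] for s in sites], SPACER_SUPPORT, alpha)
    comp_counts = np.zeros(4)
    for g in segs:
        for region in ("spacer1", "loop", "spacer2"):
            for c in g[region]:
                bases = IUPAC.get(c, "")
                if len(bases) == 1:
                    comp_counts[BASE_INDEX[bases]] += 1.0
                elif bases:
                    for b in bases:
                        comp_counts[BASE_INDEX[b]] += 1.0 / len(bases)
    comp = (comp_counts + alpha) / (comp_counts.sum() + 4.0 * alpha)
    model = AttcModel(
        pwm_R2=pwm_R2, pwm_L2=pwm_L2, pwm_L1=pwm_L1, pwm_R1=pwm_R1,
        dur_spacer1=dur_s1, dur_spacer2=dur_s2, dur_loop=dur_loop,
        region_composition=comp, background=np.full(4, 0.25),
    )
    model.validate(strict_positive=pseudocount > 0)
    return model


def read_training_tsv(path) -> list[TrainingSite]:
    """Read training sites from a TSV of id, sequence, seven segment lengths."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("id", "site_id"):
                continue
            if len(parts) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns "
                    f"(id, sequence, 7 segment lengths), got {len(parts)}")
            sites.append(TrainingSite(
                site_id=parts[0], sequence=parts[1],
                boundaries=tuple(int(x) for x in parts[2:9])))
    return sites
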