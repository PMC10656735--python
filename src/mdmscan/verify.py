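"""Primer QC, in-silico PCR, and the re-sequencing comparison rule.

Existence of a putative MDMS is supported when a specific primer pair
amplifies exactly one product from the sample template and the re-sequenced
amplicon matches the original representative at >95% identity with 100%
query cover.  Identities in (94.5, 95] are not passes but are flagged for
review, since within-OTU variation at the 97% clustering radius can place a
genuine re-observation of the same genus just under the line.

Melting temperatures come from the unified nearest-neighbor thermodynamic
model (Allawi & SantaLucia 1997 parameter set) with the entropic salt
correction 0.368 * (N-1) * ln[Na+] (SantaLucia 1998):

    Tm = 1000*dH / (dS + dS_salt + R * ln(C_T / x)) - 273.15

with R = 1.987 cal/(mol*K), x = 4 for non-self-complementary duplexes
(x = 1 plus a symmetry entropy term for self-complementary ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import config
from .pairwise import AlignmentParams, align
from .seqio import SequenceRecord

R_GAS = 1.987  # cal / (mol K)

# Allawi & SantaLucia (1997) unified NN parameters: dH kcal/mol, dS cal/(mol K)
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation with a terminal G*C / A*T pair
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)
NN_SYMMETRY_DS = -1.4  # self-complementary duplexes

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair; reverse is 5'->3' on the reverse strand."""

    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for label, p in (("fwd", self.fwd), ("rev", self.rev)):
            if not (15 <= len(p) <= 30):
                raise ValueError(f"{self.name} {label} primer length {len(p)} outside 15-30 nt")
            bad = set(p.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"{self.name} {label} primer has ambiguous bases {sorted(bad)}")
        object.__setattr__(self, "fwd", self.fwd.upper())
        object.__setattr__(self, "rev", self.rev.upper())


def gc_content(seq: str) -> float:
    """Percent G+C."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def melting_temp(seq: str, na_molar: float = 0.05, oligo_molar: float = 0.5e-6) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius."""
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("nearest-neighbor Tm model is invalid below 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError("Tm model requires unambiguous ACGT sequence")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = NN_INIT_GC if terminal in "GC" else NN_INIT_AT
        dh += h
        ds += s
    self_comp = seq == reverse_complement(seq)
    x = 1.0 if self_comp else 4.0
    if self_comp:
        ds += NN_SYMMETRY_DS
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return 1000.0 * dh / (ds + R_GAS * math.log(oligo_molar / x)) - 273.15


def self_dimer(seq: str) -> int:
    """Longest contiguous self-complementary run over all ungapped offsets.

    The sequence is slid against its own reverse complement; the score is the
    longest stretch of consecutive positions that pair.
    """
    seq = seq.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    best = 0
    for shift in range(-(n - 1), n):
        run = 0
        for i in range(n):
            j = i + shift
            if 0 <= j < n and seq[i] == rc[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


@dataclass
class PrimerReport:
    """QC metrics for one primer pair with pass/warn verdicts."""

    name: str
    fwd_gc: float
    rev_gc: float
    fwd_tm: float
    rev_tm: float
    fwd_self_dimer: int
    rev_self_dimer: int
    fwd_three_prime_clamp: bool
    rev_three_prime_clamp: bool
    tm_difference: float
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.warnings


def qc_primer_pair(pair: PrimerPair,
                   gc_min: float = config.PRIMER_GC_MIN,
                   gc_max: float = config.PRIMER_GC_MAX,
                   tm_min: float = config.PRIMER_TM_MIN,
                   tm_max: float = config.PRIMER_TM_MAX,
                   max_tm_diff: float = config.PRIMER_MAX_TM_DIFF,
                   max_self_dimer: int = config.PRIMER_MAX_SELF_DIMER) -> PrimerReport:
    """GC, Tm, self-dimer and annealing-compatibility QC for a primer pair."""
    metrics = {}
    warnings: list[str] = []
    for label, p in (("fwd", pair.fwd), ("rev", pair.rev)):
        gc = gc_content(p)
        tm = melting_temp(p)
        sd = self_dimer(p)
        metrics[label] = (gc, tm, sd, p[-1] in "GC")
        if not (gc_min <= gc <= gc_max):
            warnings.append(f"{label}_GC_OUT_OF_RANGE")
        if not (tm_min <= tm <= tm_max):
            warnings.append(f"{label}_TM_OUT_OF_RANGE")
        if sd > max_self_dimer:
            warnings.append(f"{label}_SELF_DIMER")
    tm_diff = abs(metrics["fwd"][1] - metrics["rev"][1])
    if tm_diff > max_tm_diff:
        warnings.append("TM_DIFFERENCE")
    return PrimerReport(
        name=pair.name,
        fwd_gc=metrics["fwd"][0], rev_gc=metrics["rev"][0],
        fwd_tm=metrics["fwd"][1], rev_tm=metrics["rev"][1],
        fwd_self_dimer=metrics["fwd"][2], rev_self_dimer=metrics["rev"][2],
        fwd_three_prime_clamp=metrics["fwd"][3], rev_three_prime_clamp=metrics["rev"][3],
        tm_difference=tm_diff,
        warnings=warnings,
    )


@dataclass
class PcrResult:
    amplicon: SequenceRecord | None
    reason: str               # "" on success, NO_PRODUCT or MULTIPLE_PRODUCTS
    fwd_pos: int = -1         # 0-based start of the forward primer site
    rev_end: int = -1         # 0-based exclusive end of the reverse primer site


def _mismatches(primer: str, window: str) -> int:
    return sum(1 for a, b in zip(primer, window) if a != b or a not in "ACGT")


def in_silico_pcr(pair: PrimerPair, template: SequenceRecord,
                  max_mismatches: int = config.PCR_MAX_MISMATCHES,
                  three_prime_exact: int = config.PCR_THREE_PRIME_EXACT) -> PcrResult:
    """Amplify the template with the pair; specific means exactly one product.

    The forward primer binds the plus strand; the reverse primer's reverse
    complement binds downstream.  Each site tolerates ``max_mismatches``
    but the 3'-terminal ``three_prime_exact`` bases must pair exactly
    (polymerase extension starts there).
    """
    t = template.seq
    fwd = pair.fwd
    rc_rev = reverse_complement(pair.rev)
    lf, lr = len(fwd), len(rc_rev)
    fwd_sites = []
    for p in range(0, len(t) - lf + 1):
        win = t[p:p + lf]
        if win[-three_prime_exact:] != fwd[-three_prime_exact:]:
            continue
        if _mismatches(fwd, win) <= max_mismatches:
            fwd_sites.append(p)
    rev_sites = []
    for q in range(0, len(t) - lr + 1):
        win = t[q:q + lr]
        # rev 3' end pairs with the START of its plus-strand footprint
        if win[:three_prime_exact] != rc_rev[:three_prime_exact]:
            continue
        if _mismatches(rc_rev, win) <= max_mismatches:
            rev_sites.append(q)
    products = [
        (p, q + lr)
        for p in fwd_sites
        for q in rev_sites
        if q >= p + lf
    ]
    if not products:
        return PcrResult(None, "NO_PRODUCT")
    if len(products) > 1:
        return PcrResult(None, "MULTIPLE_PRODUCTS")
    start, end = products[0]
    amp = SequenceRecord(id=f"{template.id}|amplicon|{pair.name}", seq=t[start:end])
    return PcrResult(amp, "", fwd_pos=start, rev_end=end)


@dataclass
class VerificationResult:
    mdms_id: str
    amplicon: SequenceRecord | None
    identity: float
    query_cover: float
    amplified_len: int
    passed: bool
    review: bool = False      # identity in (review_floor, pass_floor], full cover
    reason: str = ""


def compare_amplicon(amplicon: SequenceRecord, mdms_rep: SequenceRecord,
                     min_identity: float = config.VERIFY_MIN_IDENTITY,
                     required_cover: float = config.VERIFY_REQUIRED_COVER,
                     review_identity: float = config.VERIFY_REVIEW_IDENTITY,
                     params: AlignmentParams | None = None) -> VerificationResult:
    """Compare a (re-sequenced) amplicon to the original MDMS representative.

    Pass requires identity strictly above ``min_identity`` and full query
    cover of the amplicon.  Cover is local-alignment based (as BLAST
    computes query cover), so a foreign tail on the amplicon lowers it.
    """
    hit = align(amplicon, mdms_rep, params or AlignmentParams(mode="local"))
    full_cover = hit.query_coverage >= required_cover
    passed = hit.identity > min_identity and full_cover
    review = (not passed) and full_cover and review_identity < hit.identity <= min_identity
    return VerificationResult(
        mdms_id=mdms_rep.id,
        amplicon=amplicon,
        identity=hit.identity,
        query_cover=hit.query_coverage,
        amplified_len=len(amplicon.seq),
        passed=passed,
        review=review,
    )


def verify_mdms(mdms: SequenceRecord, pair: PrimerPair,
                template: SequenceRecord | None = None,
                max_mismatches: int = config.PCR_MAX_MISMATCHES,
                three_prime_exact: int = config.PCR_THREE_PRIME_EXACT,
                min_identity: float = config.VERIFY_MIN_IDENTITY,
                required_cover: float = config.VERIFY_REQUIRED_COVER,
                review_identity: float = config.VERIFY_REVIEW_IDENTITY,
                params: AlignmentParams | None = None) -> VerificationResult:
    """In-silico PCR off the template (default: the MDMS itself) + comparison."""
    template = template or mdms
    pcr = in_silico_pcr(pair, template, max_mismatches, three_prime_exact)
    if pcr.amplicon is None:
        return VerificationResult(
            mdms_id=mdms.id, amplicon=None, identity=0.0, query_cover=0.0,
            amplified_len=0, passed=False, reason=pcr.reason,
        )
    return compare_amplicon(pcr.amplicon, mdms,
                            min_identity=min_identity,
                            required_cover=required_cover,
                            review_identity=review_identity,
                            params=params)


def results_to_frame(results: Sequence[VerificationResult],
                     originals: dict[str, int] | None = None) -> pd.DataFrame:
    """Verification report with original/amplified lengths and % similarity."""
    return pd.DataFrame(
        {
            "mdms_id": [r.mdms_id for r in results],
            "original_len": [
                (originals or {}).get(r.mdms_id, 0) for r in results
            ],
            "amplified_len": [r.amplified_len for r in results],
            "identity": [round(r.identity, 4) for r in results],
            "query_cover": [round(r.query_cover, 4) for r in results],
            "passed": [r.passed for r in results],
            "review": [r.review for r in results],
            "reason": [r.reason for r in results],
        }
    )
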