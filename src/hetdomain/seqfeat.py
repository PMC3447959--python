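"""Promoter sequence features: IUPAC motif scanning with domain contrasts,
and sliding-window 9-mer melting-temperature (T_m) profiles.

Scanning is forward-strand-only over TSS-oriented windows; inverted motifs
(e.g. the inverted GAGA-factor site) are expressed as their own explicit
pattern rather than by reverse-complementing, so forward and inverted counts
stay separate. T_m uses nearest-neighbor thermodynamics with a published
unified parameter table at fixed salt and strand concentrations; absolute
values are model-dependent, comparative profiles are not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

log = logging.getLogger(__name__)

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

# nearest-neighbor T_m conditions, recorded so outputs are self-describing
TM_PARAMS = {
    "nn_table": "DNA_NN3",  # unified NN parameters (Allawi & SantaLucia)
    "Na_mM": 50.0,
    "dnac1_nM": 25.0,
    "dnac2_nM": 25.0,
    "saltcorr": 5,
}
TM_WORD = 9
TM_WINDOW_BP = 100
TM_PROFILE_LEN = TM_WINDOW_BP - TM_WORD + 1  # 92

DEFAULT_MOTIFS = {
    "TRL": ("GAGAG", (-200, 200)),
    "iTRL": ("CTCTC", (-200, 200)),
    "PB": ("KCGRWCG", (-60, 60)),
    "Inr": ("TCAGTY", (-200, 200)),
}


@dataclass(frozen=True)
class MotifSpec:
    name: str
    pattern: str
    window: tuple[int, int]  # signed bp relative to TSS

    def __post_init__(self):
        for c in self.pattern:
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r} in motif {self.name}")
        if self.window[0] >= self.window[1]:
            raise ValueError(f"motif {self.name}: window not ordered")

    @classmethod
    def default(cls, name: str) -> "MotifSpec":
        pattern, window = DEFAULT_MOTIFS[name]
        return cls(name, pattern, window)


def scan_motif(seq: str, motif: MotifSpec) -> list[int]:
    """All forward-strand start positions where ``seq`` matches the IUPAC
    pattern (overlaps allowed); N in the sequence never matches."""
    classes = [IUPAC[c] for c in motif.pattern]
    seq = seq.upper()
    m = len(classes)
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in classes[j] for j in range(m)):
            hits.append(i)
    return hits


def promoter_motif_fractions(
    promoters: dict[str, list[str]],
    motif: MotifSpec,
    tss_index: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
    contrast: tuple[str, str] | None = None,
) -> tuple[dict[str, float], float | None]:
    """Fraction of promoters per domain with >= 1 motif hit in its window,
    plus a two-sided permutation p for a two-domain contrast.

    ``promoters`` maps domain label -> TSS-oriented sequences with the TSS at
    ``tss_index``. The null shuffles domain labels over promoters;
    p = (1 + #{|null| >= |obs|}) / (1 + n_perm).
    """
    a, b = motif.window
    hits: dict[str, np.ndarray] = {}
    for dom, seqs in promoters.items():
        if not seqs:
            log.warning("promoter_motif_fractions: empty domain %s", dom)
            hits[dom] = np.empty(0, bool)
            continue
        flags = []
        for s in seqs:
            lo = max(0, tss_index + a)
            hi = min(len(s), tss_index + b)
            window_seq = s[lo:hi]
            if len(window_seq) < len(motif.pattern):
                log.warning("window shorter than motif %s", motif.name)
                flags.append(False)
            else:
                flags.append(bool(scan_motif(window_seq, motif)))
        hits[dom] = np.array(flags, bool)
    fractions = {
        dom: (float(f.mean()) if f.size else float("nan"))
        for dom, f in hits.items()
    }
    if contrast is None:
        return fractions, None
    da, db = contrast
    fa, fb = hits[da], hits[db]
    pooled = np.concatenate([fa, fb]).astype(float)
    n_a = fa.size
    obs = fa.mean() - fb.mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(pooled)
        null[i] = pooled[:n_a].mean() - pooled[n_a:].mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
    return fractions, float(p)


@lru_cache(maxsize=1 << 18)
def tm_9mer(seq: str) -> float:
    """Nearest-neighbor melting temperature (degC) of one 9-mer."""
    return float(
        mt.Tm_NN(
            seq,
            nn_table=mt.DNA_NN3,
            Na=TM_PARAMS["Na_mM"],
            dnac1=TM_PARAMS["dnac1_nM"],
            dnac2=TM_PARAMS["dnac2_nM"],
            saltcorr=TM_PARAMS["saltcorr"],
        )
    )


@dataclass
class TmProfile:
    mean_tm: np.ndarray  # per-offset mean across sequences, length 92
    n_sequences: int
    summary: dict  # min/median/mean/max over all pooled 9-mer T_m values

    def __post_init__(self):
        if self.mean_tm.size != TM_PROFILE_LEN:
            raise ValueError(f"profile length must be {TM_PROFILE_LEN}")


def tm_profile(seqs: list[str]) -> TmProfile:
    """Sliding-window 9-mer T_m over 100-bp TSS-downstream sequences.

    Sequences not exactly 100 bp are skipped (logged); windows containing N
    are skipped. The profile is the per-offset mean across sequences; the
    summary pools every computed window.
    """
    rows = []
    pooled = []
    for s in seqs:
        s = s.upper()
        if len(s) != TM_WINDOW_BP:
            log.info("tm_profile: skipping sequence of length %d", len(s))
            continue
        row = np.full(TM_PROFILE_LEN, np.nan)
        for i in range(TM_PROFILE_LEN):
            w = s[i: i + TM_WORD]
            if "N" in w:
                continue
            row[i] = tm_9mer(w)
        rows.append(row)
        pooled.extend(row[~np.isnan(row)])
    if not rows:
        raise ValueError("all sequences skipped")
    mat = np.stack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        mean_tm = np.nanmean(mat, axis=0)
    pooled = np.asarray(pooled)
    summary = {
        "min": float(pooled.min()),
        "median": float(np.median(pooled)),
        "mean": float(pooled.mean()),
        "max": float(pooled.max()),
    }
    return TmProfile(mean_tm=mean_tm, n_sequences=len(rows), summary=summary)
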