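"""miRNA seed-site scanning and AU-rich-element characterization of 3'UTRs.

The binding criterion is perfect Watson–Crick pairing between miRNA
positions 2–8 (counted 1-based from the 5' end) and the UTR, i.e. the UTR
must contain the exact reverse complement of that 7-mer. Coordinates on the
UTR are 0-based, half-open, on the 5'->3' strand. DNA input (T) is accepted
and mapped to U.

AU-rich elements are classified into the three conventional classes:
class I — dispersed AUUUA pentamers within or near a U-rich region;
class II — overlapping AUUUA pentamers near a U-rich region;
class III — a U-rich region with no AUUUA pentamer at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SeedMatch",
    "AREReport",
    "reverse_complement",
    "seed_sequence",
    "seed_sites",
    "au_fraction",
    "classify_are",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _clean_rna(seq: str, what: str = "sequence") -> str:
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid {what}: non-RNA characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    s = _clean_rna(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def seed_sequence(mirna: str) -> str:
    """The UTR 7-mer complementary to miRNA positions 2–8 (1-based, 5' end)."""
    m = _clean_rna(mirna, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt to define a 2-8 seed")
    return reverse_complement(m[1:8])


@dataclass(frozen=True)
class SeedMatch:
    """A located seed site: [start, end) on the UTR, with site AU fraction."""

    utr_id: str
    start: int
    end: int
    site_seq: str
    au_fraction: float
    region: str = "utr3"


def seed_sites(mirna: str, utr: str, utr_id: str = "utr") -> list[SeedMatch]:
    """All (possibly overlapping) exact seed-match sites on a UTR."""
    site = seed_sequence(mirna)
    u = _clean_rna(utr, "UTR")
    hits = []
    pos = u.find(site)
    while pos != -1:
        hits.append(SeedMatch(utr_id, pos, pos + 7, site, au_fraction(site)))
        pos = u.find(site, pos + 1)
    return hits


def au_fraction(seq: str) -> float:
    """(#A + #U) / length of an RNA string."""
    s = _clean_rna(seq)
    if not s:
        raise ValueError("au_fraction of an empty sequence is undefined")
    return (s.count("A") + s.count("U")) / len(s)


@dataclass(frozen=True)
class AREReport:
    utr_id: str
    n_auuua: int
    n_overlapping: int
    u_rich_windows: tuple[tuple[int, int], ...]
    are_class: str  # "I" | "II" | "III" | "none"


def _find_all(hay: str, needle: str) -> list[int]:
    out, pos = [], hay.find(needle)
    while pos != -1:
        out.append(pos)
        pos = hay.find(needle, pos + 1)
    return out


def _near(a: tuple[int, int], b: tuple[int, int], dist: int) -> bool:
    # interval gap <= dist (overlap counts as near)
    return a[0] <= b[1] + dist and b[0] <= a[1] + dist


def classify_are(
    utr: str,
    utr_id: str = "utr",
    u_rich_frac: float = 0.8,
    window: int = 10,
    near_nt: int = 20,
) -> AREReport:
    """Scan AUUUA pentamers and U-rich windows and assign an ARE class.

    U-rich windows are maximal unions of sliding ``window``-nt stretches
    whose U fraction is >= ``u_rich_frac``. Two AUUUA occurrences starting
    less than 5 nt apart count as overlapping.
    """
    u = _clean_rna(utr, "UTR")
    if len(u) < window:
        raise ValueError(f"UTR shorter than the {window}-nt scan window")
    occ = _find_all(u, "AUUUA")
    n_overlap_pairs = [
        (occ[i], occ[i + 1]) for i in range(len(occ) - 1) if occ[i + 1] - occ[i] < 5
    ]
    overlapping = sorted({p for pair in n_overlap_pairs for p in pair})

    # merged U-rich intervals
    windows: list[list[int]] = []
    for i in range(len(u) - window + 1):
        if u[i : i + window].count("U") / window >= u_rich_frac:
            if windows and i <= windows[-1][1]:
                windows[-1][1] = i + window
            else:
                windows.append([i, i + window])
    u_rich = tuple((a, b) for a, b in windows)

    are_class = "none"
    if u_rich:
        if any(
            _near((a, b + 5), w, near_nt) for a, b in n_overlap_pairs for w in u_rich
        ):
            are_class = "II"
        elif any(_near((o, o + 5), w, near_nt) for o in occ for w in u_rich):
            are_class = "I"
        else:
            are_class = "III" if not occ else "none"
    return AREReport(utr_id, len(occ), len(overlapping), u_rich, are_class)
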