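"""TSS-anchored promoter windows, IUPAC motif scanning and cross-species conservation.

Promoter windows span a region around the transcription start site in the
"+1" convention: positions run ..., -2, -1, +1, +2, ... with no position 0,
the TSS base being +1.  The default window covers 500 nt upstream and 100 nt
downstream of the TSS base, i.e. 601 nt in total.

Motifs are IUPAC consensus strings (e.g. the degenerate E-box CANNTG or the
strict 7-mer antagonist signatures CACCTGC / GCAGCTG) scanned on both strands
of the window; strictness is controlled entirely by the consensus, not by a
scoring matrix.  Conservation of a motif in a gene's promoter is called when
hits are present in at least m distinct species of the ortholog panel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to the exact base set they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {bases: code for code, bases in IUPAC_CODES.items()}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PromoterWindowSpec:
    """Extent of the promoter window around the TSS.

    ``upstream`` bases precede the TSS (positions -upstream..-1), the TSS
    base itself is +1, and ``downstream`` bases follow it; total length is
    upstream + 1 + downstream (601 with the 500/100 default).
    """

    upstream: int = 500
    downstream: int = 100

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream and downstream must be >= 0")

    @property
    def length(self) -> int:
        return self.upstream + 1 + self.downstream

    def index_to_pos(self, index: int) -> int:
        """0-based window index -> TSS-relative position (no position 0)."""
        if not 0 <= index < self.length:
            raise ValueError(f"index {index} outside window of length {self.length}")
        offset = index - self.upstream
        return offset if offset < 0 else offset + 1

    def pos_to_index(self, pos: int) -> int:
        """TSS-relative position (+1 convention) -> 0-based window index."""
        if pos == 0:
            raise ValueError("position 0 does not exist in the +1 convention")
        index = pos + self.upstream if pos < 0 else pos + self.upstream - 1
        if not 0 <= index < self.length:
            raise ValueError(f"position {pos} outside window")
        return index


@dataclass
class PromoterWindow:
    """A TSS-anchored promoter slice for one gene in one species.

    ``seq`` reads 5'->3' on the gene's coding strand.  ``tss_index`` is the
    0-based index of the TSS base within ``seq``; when it is known, hit
    coordinates are TSS-relative in the +1 convention (it is filled in
    automatically when the sequence has the full length of ``spec``).  A
    free-standing sequence with no TSS anchor (``tss_index`` left None and
    length differing from the spec) gets plain 1-based positions instead.
    """

    gene: str
    species: str
    seq: str
    spec: PromoterWindowSpec = field(default_factory=PromoterWindowSpec)
    tss_index: int | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.tss_index is None and len(self.seq) == self.spec.length:
            self.tss_index = self.spec.upstream

    def index_to_pos(self, index: int) -> int:
        """0-based index in ``seq`` -> reported coordinate (see class doc)."""
        if self.tss_index is None:
            return index + 1
        offset = index - self.tss_index
        return offset if offset < 0 else offset + 1

    def pos_to_index(self, pos: int) -> int:
        if self.tss_index is None:
            return pos - 1
        if pos == 0:
            raise ValueError("position 0 does not exist in the +1 convention")
        return pos + self.tss_index if pos < 0 else pos + self.tss_index - 1


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC consensus motif."""

    id: str
    consensus: str

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {sorted(bad)} in {self.consensus!r}")
        if len(self.consensus) < 4:
            raise ValueError("motif consensus must be at least 4 nt")
        object.__setattr__(self, "consensus", self.consensus.upper())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a promoter window.

    ``start`` is the TSS-relative position (+1 convention) of the 5'-most
    base of the match on the window's plus (coding) strand, for both
    strands; ``matched`` reads 5'->3' on the reported strand.
    """

    gene: str
    species: str
    motif: str
    start: int
    strand: str
    matched: str


@dataclass(frozen=True)
class ConservationCall:
    """Cross-species presence verdict for one gene x motif combination."""

    gene: str
    motif: str
    species_with_hit: frozenset[str]
    conserved: bool
    positional_spread: int


def iupac_matches(site: str, consensus: str) -> bool:
    """True iff `site` (plain ACGT) matches `consensus` under IUPAC semantics."""
    if len(site) != len(consensus):
        return False
    return all(b in IUPAC_CODES[c] for b, c in zip(site.upper(), consensus.upper()))


def extract_window(
    record_seq: str,
    tss: int,
    strand: str,
    spec: PromoterWindowSpec | None = None,
    gene: str = "",
    species: str = "",
) -> PromoterWindow:
    """Slice a TSS-anchored promoter window out of a longer sequence.

    Parameters
    ----------
    record_seq
        The source sequence (plus strand of a chromosome or long promoter
        record).
    tss
        0-based index of the TSS base within ``record_seq`` (the base that
        becomes position +1).  BED-style 1-based inputs must be converted by
        the caller (see :func:`notchscreen.io.read_tss_table`).
    strand
        Gene strand, ``"+"`` or ``"-"``.  For minus-strand genes the window
        is the reverse complement of the corresponding slice so the returned
        sequence always reads 5'->3' on the coding strand.

    A window extending past the record is truncated with a logged warning;
    a TSS outside the record is rejected.
    """
    spec = spec or PromoterWindowSpec()
    if not 0 <= tss < len(record_seq):
        raise ValueError(f"TSS index {tss} outside record of length {len(record_seq)}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "+":
        lo, hi = tss - spec.upstream, tss + spec.downstream + 1
    else:
        lo, hi = tss - spec.downstream, tss + spec.upstream + 1
    if lo < 0 or hi > len(record_seq):
        logger.warning(
            "window [%d, %d) truncated to record bounds [0, %d) for gene %r",
            lo, hi, len(record_seq), gene,
        )
        lo, hi = max(lo, 0), min(hi, len(record_seq))
    segment = record_seq[lo:hi].upper()
    tss_index = tss - lo
    if strand == "-":
        segment = reverse_complement(segment)
        tss_index = (hi - 1) - tss
    return PromoterWindow(gene=gene, species=species, seq=segment, spec=spec,
                          tss_index=tss_index)


def scan_motif(
    window: PromoterWindow, motif: MotifDef, both_strands: bool = True
) -> list[MotifHit]:
    """All occurrences of a motif in a window, overlapping hits included.

    Every start position is tested on the plus (coding) strand and, by
    default, on the reverse complement.  Minus-strand hits are reported at
    the plus-strand position of their 5'-most plus-strand base, with the
    matched sequence read 5'->3' on the minus strand.  Hits are ordered by
    position, plus strand before minus at equal positions.
    """
    if not window.seq:
        raise ValueError("empty promoter window")
    seq = window.seq
    m = len(motif.consensus)
    rc_consensus = _iupac_reverse_complement(motif.consensus)
    hits: list[MotifHit] = []
    for i in range(len(seq) - m + 1):
        site = seq[i : i + m]
        pos = window.index_to_pos(i)
        if iupac_matches(site, motif.consensus):
            hits.append(MotifHit(window.gene, window.species, motif.id, pos, "+", site))
        if both_strands and iupac_matches(site, rc_consensus):
            hits.append(
                MotifHit(window.gene, window.species, motif.id, pos, "-",
                         reverse_complement(site))
            )
    return hits


def _iupac_reverse_complement(consensus: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    }
    return "".join(comp[c] for c in reversed(consensus))


def derive_iupac_consensus(aligned_sites) -> str:
    """Columnwise IUPAC consensus of a gap-free set of equal-length sites.

    Each column is encoded by the IUPAC letter denoting exactly the set of
    bases observed in that column, so every input site matches the returned
    consensus and no narrower consensus does.
    """
    sites = [s.upper() for s in aligned_sites]
    if not sites:
        raise ValueError("need at least one site")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("aligned sites must all have the same length")
    bad = set("".join(sites)) - set("ACGT")
    if bad:
        raise ValueError(f"sites must be plain ACGT, found {sorted(bad)}")
    return "".join(_SET_TO_CODE[frozenset(col)] for col in zip(*sites))


def call_conservation(
    hits, species_universe, m: int | None = None
) -> list[ConservationCall]:
    """Presence-based conservation calls per gene x motif.

    A motif is conserved in a gene's promoter when hits exist in at least
    ``m`` distinct species (default: all species in the panel).  The maximum
    pairwise difference of TSS-relative start positions among supporting hits
    is reported as ``positional_spread`` but is not used as a filter.
    """
    species_universe = set(species_universe)
    if m is None:
        m = len(species_universe)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(species_universe):
        raise ValueError(f"m={m} exceeds the species panel size {len(species_universe)}")
    grouped: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        grouped.setdefault((h.gene, h.motif), []).append(h)
    calls = []
    for (gene, motif), group in sorted(grouped.items()):
        species = frozenset(h.species for h in group) & frozenset(species_universe)
        starts = [h.start for h in group if h.species in species_universe]
        spread = max((abs(a - b) for a, b in itertools.combinations(starts, 2)), default=0)
        calls.append(
            ConservationCall(gene, motif, species, len(species) >= m, spread)
        )
    return calls


def hits_to_frame(hits) -> pd.DataFrame:
    """Tabulate MotifHit records (stable, deterministic ordering)."""
    frame = pd.DataFrame(
        [(h.gene, h.species, h.motif, h.start, h.strand, h.matched) for h in hits],
        columns=["gene", "species", "motif", "start", "strand", "matched"],
    )
    return frame.sort_values(
        ["gene", "species", "motif", "start", "strand"], kind="stable"
    ).reset_index(drop=True)


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.gene, c.motif, ",".join(sorted(c.species_with_hit)),
             len(c.species_with_hit), c.conserved, c.positional_spread)
            for c in calls
        ],
        columns=["gene", "motif", "species_with_hit", "n_species", "conserved",
                 "positional_spread"],
    )


def annotate_promoter_map(
    gene: str,
    windows: dict[str, PromoterWindow],
    motifs,
    m: int | None = None,
) -> dict:
    """Full hit + conservation report for one gene across its ortholog panel.

    Scans every motif in every species window, annotates nesting between
    hits (a degenerate-site hit such as an E-box lying inside a strict 7-mer
    hit at the same location is flagged as contained in it) and attaches the
    conservation calls.  Returns ``{"gene", "hits", "conservation"}`` with
    deterministic ordering, suitable for rendering a promoter track.
    """
    motifs = list(motifs)
    all_hits: list[MotifHit] = []
    for species in sorted(windows):
        for motif in motifs:
            all_hits.extend(scan_motif(windows[species], motif))
    frame = hits_to_frame(all_hits)
    lengths = {mo.id: len(mo.consensus) for mo in motifs}
    # nesting is computed on the linear 0-based index scale of each window
    def _span(row) -> tuple[int, int]:
        lo = windows[row["species"]].pos_to_index(row["start"])
        return lo, lo + lengths[row["motif"]]

    within = []
    for _, h in frame.iterrows():
        lo, hi = _span(h)
        containers = set()
        for _, g in frame.iterrows():
            if (
                g["species"] == h["species"]
                and g["strand"] == h["strand"]
                and g["motif"] != h["motif"]
                and lengths[g["motif"]] > lengths[h["motif"]]
            ):
                glo, ghi = _span(g)
                if glo <= lo and ghi >= hi:
                    containers.add(g["motif"])
        within.append(",".join(sorted(containers)))
    frame["within"] = within
    calls = call_conservation(all_hits, {w.species for w in windows.values()}, m=m)
    return {"gene": gene, "hits": frame, "conservation": calls_to_frame(calls)}
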