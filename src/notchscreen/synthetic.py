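"""Synthetic study-condition generator with known ground truth.

Emulates the inputs of the chick DAPT screen so every pipeline stage is
testable without downloads: a one-colour intensity matrix with 4 pooled
control and 4 treated arrays, planted signed fold changes matching the
published table, a GO annotation table with one term enriched among the
upregulated genes, and orthologous TSS-anchored promoter sets carrying
planted conserved bHLH binding sites.

Noise is multiplicative log-normal on intensities (standard for one-colour
arrays and positivity-preserving); per-array global scale factors are drawn
log-uniform in [0.5, 2] so that the percentile-normalization stage is
actually exercised.  All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .expression import CONTROL, TREATED, ExpressionMatrix
from .motifs import IUPAC_CODES, PromoterWindow, PromoterWindowSpec, reverse_complement

#: (bulk-median multiples) range from which planted-gene baselines are drawn.
#: Planted genes are placed in a high-expression stratum, >= 200x the bulk
#: median, so that even the strongest planted down-regulation (1/56.83)
#: leaves them above the per-array median: no value crosses the median when
#: fold changes are applied, the per-array medians agree exactly between
#: conditions, and noise-free fold-change recovery is exact.
PLANTED_BASELINE_RANGE = (200.0, 2000.0)
BULK_MEDIAN = 100.0
BULK_LOG_SD = 0.8
SCALE_FACTOR_RANGE = (0.5, 2.0)


@dataclass
class GroundTruth:
    """Planted truth shared by all generators.

    planted_fc maps gene -> signed fold change (magnitude >= 1, sign =
    direction of change under Notch blockade); enriched_term is the GO term
    to over-represent among planted-upregulated genes (None for a null
    fixture); planted_motifs maps (gene, motif id) -> list of
    (species, TSS-relative offset, strand) placements.
    """

    planted_fc: dict[str, float] = field(default_factory=dict)
    enriched_term: str | None = None
    planted_motifs: dict[tuple[str, str], list[tuple[str, int, str]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, fc in self.planted_fc.items():
            if abs(fc) < 1:
                raise ValueError(
                    f"planted fold change for {gene} has magnitude < 1 ({fc}); "
                    "the signed convention allows no values in (-1, 1)"
                )

    def up_genes(self, cutoff: float = 1.3) -> list[str]:
        return sorted(g for g, fc in self.planted_fc.items() if fc >= cutoff)

    def down_genes(self, cutoff: float = 1.3) -> list[str]:
        return sorted(g for g, fc in self.planted_fc.items() if fc <= -cutoff)


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The published screen as ground truth.

    Fold changes are the published signed values (Notch pathway components
    plus the 23 upregulated nervous-system-development genes); the enriched
    term is nervous system development; conserved MHAM/MNAM sites are planted
    in all panel species at fixed proximal-promoter offsets.
    """
    motifs = {
        (gene, motif): [(sp, offset, "+") for sp in reference.DEFAULT_SPECIES]
        for (gene, motif), offset in reference.CONSERVED_PROMOTER_MOTIFS.items()
    }
    return GroundTruth(
        planted_fc=dict(reference.ALL_REFERENCE_FC),
        enriched_term=reference.NSD_TERM,
        planted_motifs=motifs,
        seed=seed,
    )


def _planted_ratio(fc: float) -> float:
    """Signed fold change -> treated/control intensity ratio."""
    return fc if fc >= 1 else 1.0 / abs(fc)


def generate_expression(
    truth: GroundTruth,
    n_genes: int = 2000,
    n_control: int = 4,
    n_treated: int = 4,
    noise_sd: float = 0.1,
    scale_factors=None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Gene-by-sample intensity matrix with the truth's fold changes planted.

    Control intensities are log-normal around a per-gene baseline; treated
    intensities are the baseline multiplied by the planted ratio (FC if
    positive else 1/|FC|).  Per-array scale factors default to log-uniform
    draws in [0.5, 2] (pass ``1.0`` or a sequence to pin them).

    With ``noise_sd=0`` and unit scale factors the raw treated/control ratio
    of means equals the planted ratio exactly for every planted gene; with
    drawn scale factors the same exactness holds after percentile
    normalization, which cancels per-array scale.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_control < 1 or n_treated < 1:
        raise ValueError("need at least one replicate per condition")
    planted = sorted(truth.planted_fc)
    if n_genes < len(planted):
        raise ValueError(f"n_genes={n_genes} < {len(planted)} planted genes")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    n_bulk = n_genes - len(planted)
    genes = planted + [f"GENE{i:05d}" for i in range(n_bulk)]
    baselines = np.concatenate(
        [
            BULK_MEDIAN * np.exp(rng.uniform(*np.log(PLANTED_BASELINE_RANGE), len(planted))),
            rng.lognormal(np.log(BULK_MEDIAN), BULK_LOG_SD, n_bulk),
        ]
    )
    ratios = np.ones(n_genes)
    ratios[: len(planted)] = [_planted_ratio(truth.planted_fc[g]) for g in planted]

    n_samples = n_control + n_treated
    if scale_factors is None:
        scales = np.exp(rng.uniform(*np.log(SCALE_FACTOR_RANGE), n_samples))
    else:
        scales = np.broadcast_to(np.asarray(scale_factors, dtype=float), (n_samples,))
    noise = np.exp(rng.normal(0.0, noise_sd, (n_genes, n_samples))) if noise_sd > 0 else 1.0

    expected = np.outer(baselines, np.ones(n_samples))
    expected[:, n_control:] *= ratios[:, None]
    intensities = expected * noise * scales

    samples = [f"{CONTROL}_{i + 1}" for i in range(n_control)] + [
        f"{TREATED}_{i + 1}" for i in range(n_treated)
    ]
    conditions = pd.Series(
        [CONTROL] * n_control + [TREATED] * n_treated, index=samples
    )
    return ExpressionMatrix(
        pd.DataFrame(intensities, index=pd.Index(genes, name="gene"), columns=samples),
        conditions,
    )


def generate_go_annotation(
    truth: GroundTruth,
    n_terms: int,
    genes,
    enriched_size: int = 10,
    enriched_overlap: int = 8,
    term_size_range: tuple[int, int] = (5, 30),
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-to-GO-term pair table with one term enriched by construction.

    When the truth carries an enriched term, that term annotates
    ``enriched_size`` genes of which ``enriched_overlap`` come from the
    planted-upregulated set, so its overlap with the up list exceeds random
    expectation by construction.  The remaining terms annotate uniformly
    sampled gene sets.  ``n_terms`` is the total number of terms, the
    enriched one included.
    """
    genes = list(genes)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if n_terms == 0:
        return pd.DataFrame(columns=["gene", "term"])
    rows: list[tuple[str, str]] = []
    n_background = n_terms
    if truth.enriched_term is not None:
        if enriched_overlap > enriched_size:
            raise ValueError(
                f"overlap {enriched_overlap} larger than term size {enriched_size}"
            )
        up = [g for g in truth.up_genes() if g in set(genes)]
        if enriched_overlap > len(up):
            raise ValueError(
                f"overlap {enriched_overlap} exceeds the {len(up)} planted-up genes"
            )
        non_up = [g for g in genes if g not in set(up)]
        members = list(rng.choice(up, enriched_overlap, replace=False)) + list(
            rng.choice(non_up, enriched_size - enriched_overlap, replace=False)
        )
        rows += [(g, truth.enriched_term) for g in sorted(members)]
        n_background -= 1
    lo, hi = term_size_range
    for i in range(n_background):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, min(size, len(genes)), replace=False)
        rows += [(g, f"GO:{7000000 + i:07d}") for g in sorted(members)]
    return pd.DataFrame(rows, columns=["gene", "term"])


def _resolve_iupac(consensus: str, rng: np.random.Generator) -> str:
    """Pick a concrete ACGT instance of an IUPAC consensus."""
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in consensus)


def generate_ortholog_promoters(
    truth: GroundTruth,
    species=reference.DEFAULT_SPECIES,
    spec: PromoterWindowSpec | None = None,
    genes=None,
    motif_strings: dict[str, str] | None = None,
    gc: float = 0.5,
    seed: int | None = None,
) -> list[PromoterWindow]:
    """Per-gene, per-species promoter windows with planted binding sites.

    Background sequence is i.i.d. with the configured GC content (uniform
    25% per base by default); each planted motif instance overwrites the
    background at its TSS-relative offset, reverse-complemented for minus-
    strand placements.  Genes default to those carrying planted motifs.
    """
    spec = spec or PromoterWindowSpec()
    motif_strings = dict(reference.MOTIFS if motif_strings is None else motif_strings)
    if genes is None:
        genes = sorted({gene for gene, _ in truth.planted_motifs})
    genes = list(genes)
    if not 0 <= gc <= 1:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T

    windows: dict[tuple[str, str], list[str]] = {}
    for gene in genes:
        for sp in species:
            windows[(gene, sp)] = list(
                "".join(rng.choice(list("ACGT"), spec.length, p=probs))
            )
    for (gene, motif_id), placements in sorted(truth.planted_motifs.items()):
        consensus = motif_strings[motif_id]
        for sp, offset, strand in placements:
            if (gene, sp) not in windows:
                continue
            idx = spec.pos_to_index(offset)
            if idx + len(consensus) > spec.length:
                raise ValueError(
                    f"motif {motif_id} at offset {offset} exceeds the "
                    f"{spec.length} nt window for gene {gene}"
                )
            site = _resolve_iupac(consensus, rng)
            if strand == "-":
                site = reverse_complement(site)
            windows[(gene, sp)][idx : idx + len(site)] = site
    return [
        PromoterWindow(gene=gene, species=sp, seq="".join(chars), spec=spec)
        for (gene, sp), chars in windows.items()
    ]


def expected_background_hits(window_length: int, motif_length: int) -> float:
    """Closed-form expected both-strand hit count for a strict motif.

    On i.i.d. uniform sequence a strict k-mer matches a given start with
    probability (1/4)^k per strand, giving
    2 (L - k + 1) (1/4)^k expected hits over a window of length L.
    """
    return 2 * (window_length - motif_length + 1) * 0.25**motif_length
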