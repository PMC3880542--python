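"""End-to-end orchestration of the Notch-target discovery screen.

Runs synthesize -> normalize/fold-change screen -> GO over-representation ->
promoter motif conservation, then joins the upregulated genes to their
conserved binding-site signatures and checks the observed directions of the
known pathway genes against the lateral-inhibition regulatory model
(DLL1 -> NOTCH -> HES5/HEY1 -| ASCL1 -> DLL1/NHLH1/targets).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io, reference
from .enrichment import enrich
from .expression import classify, fold_change, normalize_percentile, partition_by_cutoff
from .motifs import MotifDef, PromoterWindowSpec, call_conservation, calls_to_frame, hits_to_frame, scan_motif
from .synthetic import (
    GroundTruth,
    default_ground_truth,
    generate_expression,
    generate_go_annotation,
    generate_ortholog_promoters,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; serializable to/from YAML."""

    seed: int = 0
    n_genes: int = 2000
    n_control: int = 4
    n_treated: int = 4
    noise_sd: float = 0.1
    cutoff: float = 1.3
    percentile: float = 50.0
    alpha: float = 0.05
    n_terms: int = 50
    upstream: int = 500
    downstream: int = 100
    min_species: int | None = None  # None = all species in the panel
    species: tuple[str, ...] = reference.DEFAULT_SPECIES
    conservation_motifs: tuple[str, ...] = ("MHAM", "MNAM")
    scan_motifs: tuple[str, ...] = ("EBOX", "NBOX", "MHAM", "MNAM")
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.species = tuple(self.species)
        self.conservation_motifs = tuple(self.conservation_motifs)
        self.scan_motifs = tuple(self.scan_motifs)

    @property
    def window_spec(self) -> PromoterWindowSpec:
        return PromoterWindowSpec(self.upstream, self.downstream)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RegulatoryModelTable:
    """Static directed interaction model of the lateral-inhibition circuit."""

    edges: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(reference.REGULATORY_EDGES)
    )

    def expected_directions(self) -> dict[str, str]:
        """Directions implied by the model when NOTCH is blocked.

        Signs are propagated from NOTCH=down through activating (sign kept)
        and repressing (sign flipped) edges; edges into NOTCH are cut since
        the blockade is downstream of ligand binding.  Keys are upper-case
        gene symbols.
        """
        directions: dict[str, str] = {"NOTCH": "down"}
        changed = True
        while changed:
            changed = False
            for src, dst, sign in self.edges:
                if dst == "NOTCH" or src not in directions or dst in directions:
                    continue
                implied = directions[src]
                if sign == "represses":
                    implied = "down" if implied == "up" else "up"
                directions[dst] = implied
                changed = True
        return directions


@dataclass
class RunReport:
    config: PipelineConfig
    truth: GroundTruth
    de_table: pd.DataFrame
    counts: dict[str, int]
    enrichment: pd.DataFrame
    hits: pd.DataFrame
    conservation: pd.DataFrame
    summary: pd.DataFrame
    consistency: pd.DataFrame
    n_violations: int
    paths: dict[str, Path]


def consistency_check(
    de_table: pd.DataFrame, expected: dict[str, str] | None = None
) -> pd.DataFrame:
    """Compare observed fold-change signs with the expected Notch-blockade pattern.

    ``expected`` maps gene -> ``up``/``down``; defaults to the published
    direction table.  The comparison is on the sign of the fold change
    (up: fc > 1, down: fc < -1), not on the screening cutoff, so borderline
    genes are judged by direction alone.  Genes absent from the DE table are
    reported as ``untestable``, never as errors.  Status per gene is
    ``consistent``, ``violation`` or ``untestable``.
    """
    expected = dict(reference.EXPECTED_DIRECTION if expected is None else expected)
    fc = de_table.set_index("gene")["fc_signed"]
    rows = []
    for gene in sorted(expected):
        if gene not in fc.index:
            status = "untestable"
            obs = ""
        else:
            value = fc[gene]
            obs = "up" if value > 1 else ("down" if value < -1 else "unchanged")
            status = "consistent" if obs == expected[gene] else "violation"
        rows.append((gene, expected[gene], obs, status))
    return pd.DataFrame(rows, columns=["gene", "expected", "observed", "status"])


def run_pipeline(config: PipelineConfig, truth: GroundTruth | None = None) -> RunReport:
    """Execute every stage on synthetic inputs and write all result tables.

    Stages and their outputs (all TSV unless noted, under ``config.out_dir``):
    expression matrix (+condition sidecar), DE table, enrichment table,
    promoter FASTA, motif hit and conservation tables, the up-genes x
    conserved-motifs summary, and the regulatory-model consistency report.
    Two runs with the same config and seed produce byte-identical files.
    """
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    params = {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}
    truth = default_ground_truth(config.seed) if truth is None else truth
    paths: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage %s (t=%.2fs)", name, time.perf_counter() - t0)

    try:
        _stage("synthesize")
        matrix = generate_expression(
            truth,
            n_genes=config.n_genes,
            n_control=config.n_control,
            n_treated=config.n_treated,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        paths["expression"] = out / "expression.tsv"
        paths["conditions"] = out / "conditions.tsv"
        io.write_expression(matrix, paths["expression"], paths["conditions"], params)
    except Exception as exc:
        raise RuntimeError(f"stage synthesize failed: {exc}") from exc

    try:
        _stage("de")
        normalized = normalize_percentile(matrix, config.percentile)
        fcr = fold_change(normalized)
        for gene, why in fcr.rejected.items():
            logger.warning("gene %s rejected: %s", gene, why)
        de_table = classify(fcr.fc_signed, config.cutoff)
        up, down, unchanged = partition_by_cutoff(de_table, config.cutoff)
        counts = {"up": len(up), "down": len(down), "unchanged": len(unchanged)}
        ordered = pd.concat([up, down, unchanged], ignore_index=True)
        paths["de"] = out / "de.tsv"
        io.write_table(ordered, paths["de"], params)
    except Exception as exc:
        raise RuntimeError(f"stage de failed: {exc}") from exc

    try:
        _stage("enrichment")
        annotation = generate_go_annotation(
            truth, config.n_terms, list(matrix.genes), seed=config.seed
        )
        paths["annotation"] = out / "annotation.tsv"
        io.write_go_table(annotation, paths["annotation"], params)
        enrichment = enrich(
            up["gene"], annotation, alpha=config.alpha, universe=list(matrix.genes)
        )
        paths["enrichment"] = out / "enrichment.tsv"
        io.write_table(enrichment, paths["enrichment"], params)
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    try:
        _stage("motifs")
        windows = generate_ortholog_promoters(
            truth, species=config.species, spec=config.window_spec, seed=config.seed
        )
        paths["promoters"] = out / "promoters.fasta"
        io.write_promoters(windows, paths["promoters"])
        motif_defs = [MotifDef(mid, reference.MOTIFS[mid]) for mid in config.scan_motifs]
        all_hits = [h for w in windows for mo in motif_defs for h in scan_motif(w, mo)]
        hits = hits_to_frame(all_hits)
        paths["hits"] = out / "motif_hits.tsv"
        io.write_table(hits, paths["hits"], params)
        strict_hits = [h for h in all_hits if h.motif in config.conservation_motifs]
        calls = call_conservation(strict_hits, set(config.species), m=config.min_species)
        conservation = calls_to_frame(calls)
        paths["conservation"] = out / "conservation.tsv"
        io.write_table(conservation, paths["conservation"], params)
    except Exception as exc:
        raise RuntimeError(f"stage motifs failed: {exc}") from exc

    try:
        _stage("summary")
        conserved = conservation[conservation["conserved"]]
        summary = up.merge(conserved, on="gene", how="inner").sort_values(
            ["gene", "motif"], kind="stable"
        ).reset_index(drop=True)
        paths["summary"] = out / "summary.tsv"
        io.write_table(summary, paths["summary"], params)

        consistency = consistency_check(de_table)
        n_violations = int((consistency["status"] == "violation").sum())
        paths["consistency"] = out / "consistency.tsv"
        io.write_table(consistency, paths["consistency"], params)
    except Exception as exc:
        raise RuntimeError(f"stage summary failed: {exc}") from exc

    _stage("done")
    return RunReport(
        config=config,
        truth=truth,
        de_table=de_table,
        counts=counts,
        enrichment=enrichment,
        hits=hits,
        conservation=conservation,
        summary=summary,
        consistency=consistency,
        n_violations=n_violations,
        paths=paths,
    )
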