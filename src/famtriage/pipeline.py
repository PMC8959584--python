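"""End-to-end orchestration: config in, prioritization report out.

``run_triage`` wires the stages together: read inputs -> site QC -> rare-
variant cascade -> segregation selection -> pedigree IBD verification (when
parental links exist) -> case-control association (when labels are
supplied). Results are returned as a :class:`TriageReport` and optionally
written as a TSV candidate table plus a JSON summary; a stage failure
aborts the run and removes partial outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import AssociationResult, genotype_association
from .prioritize import CascadeReport, FilterConfig, run_cascade
from .qc import QcThresholds
from .relatedness import PairCheck, pedigree_ibd_check
from .variant_io import (
    DEFAULT_DIALECT,
    read_annotated_vcf,
    read_bed_mask,
    read_pedigree,
)

logger = logging.getLogger("famtriage")


@dataclass
class RunConfig:
    """Everything one triage run needs; recorded (hashed) in the report."""

    vcf: str
    ped: str
    repeat_bed: str | None = None
    labels_tsv: str | None = None  # two columns: sample, case/control
    out_dir: str | None = None
    models: tuple[str, ...] = ("compound_het", "hom_recessive")
    qc: QcThresholds = field(default_factory=QcThresholds)
    filters: FilterConfig = field(default_factory=FilterConfig)
    ibd_bounds: tuple[float, float] = (0.45, 0.55)
    association_rule: str = "carrier"
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of everything that affects the numbers (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TriageReport:
    cascade: CascadeReport
    ibd_checks: list[PairCheck]
    associations: dict[str, AssociationResult]
    provenance: dict

    @property
    def candidate_genes(self) -> dict[str, list[str]]:
        return self.cascade.candidate_genes

    def candidate_table(self) -> pd.DataFrame:
        """One row per (model, candidate variant)."""
        rows = []
        variants = {v.key: v for v in self.cascade.final_variants}
        for model, cands in self.cascade.models.items():
            for cand in cands:
                for k in cand.variant_keys:
                    v = variants.get(k)
                    harm, verdict = self.cascade.vote_results.get(k, (None, None))
                    rows.append(
                        {
                            "model": model,
                            "gene": cand.gene,
                            "variant": k,
                            "rsid": v.rsid if v else None,
                            "harm_count": harm,
                            "verdict": verdict,
                            "acmg_class": self.cascade.acmg_classes.get(k),
                            "affected_carriers": ";".join(
                                s for s, ks in cand.affected_carriers.items() if k in ks
                            ),
                            "incomplete": cand.incomplete,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "model", "gene", "variant", "rsid", "harm_count", "verdict",
                "acmg_class", "affected_carriers", "incomplete",
            ],
        )

    def summary(self) -> dict:
        return {
            "provenance": self.provenance,
            "stage_counts": self.cascade.stage_counts,
            "candidate_genes": self.candidate_genes,
            "ibd_checks": [
                {
                    "parent": c.parent,
                    "child": c.child,
                    "pi_hat": c.estimate.pi_hat,
                    "z": [c.estimate.z0, c.estimate.z1, c.estimate.z2],
                    "n_sites": c.estimate.n_sites_used,
                    "passed": c.passed,
                }
                for c in self.ibd_checks
            ],
            "associations": {
                key: {
                    "case_rate_percent": r.case_rate,
                    "control_rate_percent": r.control_rate,
                    "odds_ratio": r.odds_ratio,
                    "chi2_p": r.chi2_p,
                    "chi2_yates_p": r.chi2_yates_p,
                    "fisher_p": r.fisher_p,
                    "test_used": r.test_used,
                }
                for key, r in self.associations.items()
            },
        }


def _read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: labels must be 'case' or 'control', found {sorted(bad)}")
    return dict(zip(df["sample"], df["group"]))


def run_triage(config: RunConfig) -> TriageReport:
    """Execute the full pipeline described by ``config``.

    Deterministic given the seed; the report's provenance block records the
    config hash so a rerun with identical inputs reproduces it byte for
    byte.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    written: list[Path] = []
    try:
        logger.info("[stage:read] loading inputs")
        for name, p in (("vcf", config.vcf), ("ped", config.ped)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
        variants, genotypes = read_annotated_vcf(config.vcf, DEFAULT_DIALECT)
        pedigree = read_pedigree(config.ped)
        mask = read_bed_mask(config.repeat_bed) if config.repeat_bed else None
        labels = _read_labels(config.labels_tsv) if config.labels_tsv else None

        logger.info("[stage:cascade] %d variants in", len(variants))
        cascade = run_cascade(
            variants,
            genotypes,
            pedigree,
            config.filters,
            repeat_mask=mask,
            models=config.models,
            qc_thresholds=config.qc,
        )
        logger.info("[stage:cascade] counts %s", cascade.stage_counts)

        ibd_checks: list[PairCheck] = []
        if pedigree.parent_offspring_pairs():
            logger.info("[stage:ibd] verifying declared parent-offspring pairs")
            ibd_checks = pedigree_ibd_check(genotypes, pedigree, config.ibd_bounds)

        associations: dict[str, AssociationResult] = {}
        if labels:
            logger.info("[stage:association] %d labeled samples", len(labels))
            for v in variants:
                if set(genotypes.sample_ids) <= set(labels):
                    associations[v.key] = genotype_association(
                        genotypes, labels, config.association_rule, v.key
                    )

        report = TriageReport(
            cascade=cascade,
            ibd_checks=ibd_checks,
            associations=associations,
            provenance={
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "famtriage_version": __version__,
            },
        )
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            tsv = out_dir / "candidates.tsv"
            js = out_dir / "summary.json"
            written = [tsv, js]
            report.candidate_table().to_csv(tsv, sep="\t", index=False)
            js.write_text(json.dumps(report.summary(), indent=2, sort_keys=True) + "\n")
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
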