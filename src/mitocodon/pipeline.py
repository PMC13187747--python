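"""End-to-end orchestration: QC -> metrics -> RSCU -> multivariate ->
skews -> ENC-GC3/neutrality -> CAI -> coadaptation -> bundled outputs.

`run_pipeline` executes the full analysis on either a synthetic cohort spec
or on-disk inputs (GenBank mitogenomes + nuclear FASTA + metadata TSV) and
writes a deterministic output bundle: tidy CSV tables, fit/test JSON, plots,
a run log and a config snapshot.  Re-running with an identical config and
inputs produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .codon_metrics import (
    compute_cai,
    compute_rscu,
    count_codons,
    gene_metrics,
    merge_counts,
    reference_weights,
)
from .mitonuclear import coadaptation_table
from .multivariate import (
    assemble_matrix,
    dispersion_test,
    hierarchical_order,
    pca,
    permanova,
    zscore_columns,
)
from .selection import (
    DEFAULT_SEED,
    bootstrap_slope,
    enc_deviation,
    enc_expected,
    order_level_test,
)
from .sequence_io import (
    CANONICAL_MITO_GENES,
    QCPolicy,
    SpeciesRecord,
    qc_filter,
    read_fasta_cds,
    read_genbank_cds,
)
from .simulate import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "OutputBundle", "run_pipeline", "write_report"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    cohort: CohortSpec | None = None
    input_dir: str | None = None           # expects metadata.tsv layout
    outdir: str = "mitocodon_out"
    qc: QCPolicy = field(default_factory=QCPolicy)
    codon_set_mode: str = "paper_compat_60"
    permutations: int = 10_000
    bootstrap_B: int = 10_000
    seed: int = DEFAULT_SEED
    paper_compat_cai_zero: bool = False    # write 0 instead of NA for absent genes
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            raise ValueError("config needs either a cohort spec or an input_dir")
        if self.permutations < 0 or self.bootstrap_B < 0:
            raise ValueError("permutations and bootstrap_B must be >= 0")

    def snapshot(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                d = {}
                for f in dataclasses.fields(obj):
                    if f.name in ("code", "preference_weights", "aa_composition"):
                        continue
                    d[f.name] = clean(getattr(obj, f.name))
                if hasattr(obj, "code"):
                    d["table_id"] = obj.code.table_id
                return d
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            return obj

        return clean(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class OutputBundle:
    outdir: Path
    gene_metrics: pd.DataFrame
    species_metrics: pd.DataFrame
    rscu_long: pd.DataFrame
    cai_matrix: pd.DataFrame
    enc_gc3_points: pd.DataFrame
    neutrality: dict
    order_tests: pd.DataFrame
    permanova: dict
    coadaptation: pd.DataFrame
    log_lines: list[str]
    config: PipelineConfig


def _load_species(config: PipelineConfig, log: list[str]) -> list[SpeciesRecord]:
    if config.cohort is not None:
        records, _ = generate_cohort(config.cohort)
        log.append(f"simulated cohort: {len(records)} species, seed {config.cohort.seed}")
        return records
    base = Path(config.input_dir)
    meta = pd.read_csv(base / "metadata.tsv", sep="\t")
    records = []
    for _, row in meta.iterrows():
        rec = SpeciesRecord(row["species_id"], row["order_label"])
        if isinstance(row.get("mito_path"), str):
            rec.mito_genes = read_genbank_cds(
                base / row["mito_path"], species_id=row["species_id"]
            )
        if isinstance(row.get("nuclear_path"), str):
            rec.nuclear_genes = read_fasta_cds(
                base / row["nuclear_path"], species_id=row["species_id"]
            )
        records.append(rec)
    log.append(f"loaded {len(records)} species from {base}")
    return records


def run_pipeline(config: PipelineConfig) -> OutputBundle:
    """Execute all stages and write the output bundle under ``config.outdir``.

    A species whose compartments entirely fail QC is dropped with a logged
    reason, never silently; if no species survives, the run aborts with a
    summary.  ``permutations=0`` skips the PERMANOVA stage explicitly.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        "mitocodon 0.1.0",
        f"seed {config.seed}",
        f"config hash {config.config_hash()}",
    ]

    records = _load_species(config, log)

    # ---- QC ---------------------------------------------------------------
    survivors: list[SpeciesRecord] = []
    qc_frames = []
    for rec in records:
        mito, log_m = qc_filter(rec.mito_genes, config.qc)
        nuc, log_n = qc_filter(rec.nuclear_genes, config.qc)
        qc_frames += [log_m.to_frame(), log_n.to_frame()]
        if not mito and not nuc:
            log.append(f"species {rec.species_id} dropped: no CDS survived QC")
            continue
        survivors.append(
            SpeciesRecord(rec.species_id, rec.order_label, mito, nuc)
        )
    if not survivors:
        raise RuntimeError(
            f"no species surviving QC (started with {len(records)}); "
            "see rejection log"
        )
    pd.concat(qc_frames, ignore_index=True).to_csv(
        outdir / "qc_rejections.tsv", sep="\t", index=False
    )

    # ---- per-gene and per-species metrics, RSCU, CAI ----------------------
    gene_rows, species_rows, rscu_rows = [], [], []
    enc_points = []
    cai_cells = []
    profiles = {"mito": [], "nuclear": []}
    coadapt_profiles = {}
    for rec in survivors:
        per_species_rscu = {}
        for comp in ("mito", "nuclear"):
            genes = rec.genes(comp)
            if not genes:
                continue
            counts = [count_codons(g) for g in genes]
            pooled = merge_counts(counts, f"{rec.species_id}/{comp}/pooled")
            weights = reference_weights(pooled) if comp == "mito" else None
            for g, ct in zip(genes, counts):
                gm = gene_metrics(g, weights=weights)
                gene_rows.append(
                    {
                        "unit_id": gm.unit_id,
                        "species_id": rec.species_id,
                        "order_label": rec.order_label,
                        "compartment": comp,
                        "gene": g.gene,
                        **{
                            k: getattr(gm, k)
                            for k in (
                                "enc", "gc1", "gc2", "gc3", "gc12", "gc3s",
                                "at_skew", "gc_skew", "gc_content",
                                "at_content", "cai", "n_codons",
                            )
                        },
                    }
                )
                if (
                    not math.isnan(gm.enc)
                    and not math.isnan(gm.gc3s)
                    and gm.n_codons >= config.qc.min_codons_for_enc
                ):
                    enc_points.append(
                        {
                            "unit_id": gm.unit_id,
                            "species_id": rec.species_id,
                            "order_label": rec.order_label,
                            "compartment": comp,
                            "enc": gm.enc,
                            "gc3s": gm.gc3s,
                            "gc12": gm.gc12,
                            "gc3": gm.gc3,
                            "n_codons": gm.n_codons,
                        }
                    )
                if comp == "mito" and g.gene in CANONICAL_MITO_GENES:
                    cai_cells.append(
                        {
                            "species_id": rec.species_id,
                            "order_label": rec.order_label,
                            "gene": g.gene,
                            "cai": compute_cai(ct, weights),
                        }
                    )
            concat = rec.concatenated(comp)
            sm = gene_metrics(
                concat,
                weights=weights if comp == "mito" else None,
                unit_id=f"{rec.species_id}/{comp}",
            )
            species_rows.append(
                {
                    "species_id": rec.species_id,
                    "order_label": rec.order_label,
                    "compartment": comp,
                    **{
                        k: getattr(sm, k)
                        for k in (
                            "enc", "gc1", "gc2", "gc3", "gc12", "gc3s",
                            "at_skew", "gc_skew", "gc_content", "at_content",
                            "cai", "n_codons",
                        )
                    },
                }
            )
            prof = compute_rscu(
                merge_counts(counts, f"{rec.species_id}/{comp}")
            )
            profiles[comp].append(prof)
            per_species_rscu[comp] = prof
            for codon, v in sorted(prof.rscu.items()):
                rscu_rows.append(
                    {
                        "unit_id": prof.unit_id,
                        "species_id": rec.species_id,
                        "compartment": comp,
                        "codon": codon,
                        "amino_acid": prof.code.translate_codon(codon),
                        "rscu": v,
                    }
                )
        if "mito" in per_species_rscu and "nuclear" in per_species_rscu:
            coadapt_profiles[rec.species_id] = (
                per_species_rscu["mito"],
                per_species_rscu["nuclear"],
            )

    gene_df = pd.DataFrame(gene_rows)
    species_df = pd.DataFrame(species_rows)
    rscu_df = pd.DataFrame(rscu_rows)
    gene_df.to_csv(outdir / "gene_metrics.csv", index=False, float_format=_FLOAT_FMT)
    species_df.to_csv(outdir / "species_metrics.csv", index=False, float_format=_FLOAT_FMT)
    rscu_df.to_csv(outdir / "rscu_long.csv", index=False, float_format=_FLOAT_FMT)

    cai_df = pd.DataFrame(cai_cells)
    if not cai_df.empty:
        cai_matrix = cai_df.pivot_table(
            index="species_id", columns="gene", values="cai", aggfunc="mean"
        ).reindex(columns=list(CANONICAL_MITO_GENES))
        if config.paper_compat_cai_zero:
            cai_matrix = cai_matrix.fillna(0.0)
    else:
        cai_matrix = pd.DataFrame(columns=list(CANONICAL_MITO_GENES))
    cai_matrix.to_csv(outdir / "cai_matrix.csv", float_format=_FLOAT_FMT)

    # ---- multivariate (mito compartment) ----------------------------------
    matrix = assemble_matrix(profiles["mito"], codon_set_mode=config.codon_set_mode)
    scaled = zscore_columns(matrix)
    scaled.values.to_csv(outdir / "rscu_matrix.csv", float_format=_FLOAT_FMT)
    ord_res = pca(scaled)
    ord_res.scores.to_csv(outdir / "pca_scores.csv", float_format=_FLOAT_FMT)
    ord_res.loadings.to_csv(outdir / "pca_loadings.csv", float_format=_FLOAT_FMT)
    leaf_order, _ = hierarchical_order(scaled)
    log.append(f"heatmap row order: {leaf_order[:10]}...")

    labels = [u.split("/")[0] for u in scaled.units]
    order_of = {r.species_id: r.order_label for r in survivors}
    group_labels = [order_of[s] for s in labels]
    perm_out: dict = {"skipped": True}
    if config.permutations > 0 and len(set(group_labels)) >= 2:
        perm = permanova(
            scaled, group_labels,
            permutations=config.permutations, seed=config.seed,
        )
        disp_p = dispersion_test(
            scaled, group_labels,
            permutations=config.permutations, seed=config.seed,
        )
        perm.dispersion_p = disp_p
        perm_out = dataclasses.asdict(perm)
    else:
        log.append("PERMANOVA stage skipped (permutations=0 or <2 groups)")
    with open(outdir / "permanova.json", "w") as fh:
        json.dump(perm_out, fh, indent=1, sort_keys=True)

    # ---- ENC-GC3 / neutrality ---------------------------------------------
    points_df = pd.DataFrame(enc_points)
    neutrality: dict = {}
    if not points_df.empty:
        dev = enc_deviation(points_df)
        dev.points.to_csv(outdir / "enc_gc3_points.csv", index=False,
                          float_format=_FLOAT_FMT)
        for comp in points_df["compartment"].unique():
            sub = dev.points[dev.points["compartment"] == comp]
            if len(sub) >= 3 and sub["species_id"].nunique() >= 2 and sub["gc3"].nunique() > 1:
                fit = bootstrap_slope(
                    sub, B=config.bootstrap_B, seed=config.seed,
                )
                neutrality[comp] = dataclasses.asdict(fit)
        neutrality["fraction_below_curve"] = dev.fraction_below_curve
    with open(outdir / "neutrality_fit.json", "w") as fh:
        json.dump(neutrality, fh, indent=1, sort_keys=True)

    # ---- order-level tests -------------------------------------------------
    tests_df = pd.DataFrame()
    mito_genes_df = gene_df[gene_df["compartment"] == "mito"]
    if mito_genes_df["order_label"].nunique() >= 2:
        try:
            results = order_level_test(
                mito_genes_df, ["enc", "gc3", "cai", "at_skew", "gc_skew"]
            )
            tests_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        except ValueError as exc:
            log.append(f"order-level tests skipped: {exc}")
    tests_df.to_csv(outdir / "order_tests.csv", index=False, float_format=_FLOAT_FMT)

    # ---- coadaptation ------------------------------------------------------
    coadapt_df = (
        coadaptation_table(coadapt_profiles) if coadapt_profiles else pd.DataFrame()
    )
    coadapt_df.to_csv(outdir / "coadaptation.csv", index=False, float_format=_FLOAT_FMT)

    # ---- plots -------------------------------------------------------------
    if config.make_plots:
        try:
            _make_plots(outdir, scaled, ord_res, points_df, group_labels, leaf_order)
        except Exception as exc:  # plotting must never kill an analysis run
            log.append(f"plotting failed: {exc}")

    with open(outdir / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(config.snapshot(), fh, sort_keys=True)
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")

    return OutputBundle(
        outdir=outdir,
        gene_metrics=gene_df,
        species_metrics=species_df,
        rscu_long=rscu_df,
        cai_matrix=cai_matrix,
        enc_gc3_points=points_df,
        neutrality=neutrality,
        order_tests=tests_df,
        permanova=perm_out,
        coadaptation=coadapt_df,
        log_lines=log,
        config=config,
    )


def _make_plots(outdir, scaled, ord_res, points_df, group_labels, leaf_order):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    # heat map of z-scored RSCU, rows in dendrogram order
    fig, ax = plt.subplots(figsize=(10, 6))
    data = scaled.values.iloc[leaf_order]
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdPu")
    ax.set_xticks(range(0, data.shape[1], 5))
    ax.set_xticklabels(data.columns[::5], rotation=90, fontsize=6)
    ax.set_yticks(range(len(data)))
    ax.set_yticklabels(data.index, fontsize=5)
    fig.colorbar(im, label="RSCU (z-score)")
    fig.tight_layout()
    fig.savefig(outdir / "heatmap.png", dpi=120)
    plt.close(fig)

    # PCA biplot with per-group confidence ellipses
    fig, ax = plt.subplots(figsize=(7, 6))
    scores = ord_res.scores
    groups = np.asarray(group_labels)
    for g in np.unique(groups):
        pts = scores.to_numpy()[groups == g, :2]
        ax.scatter(pts[:, 0], pts[:, 1], label=g, s=18)
        if len(pts) >= 3:
            _confidence_ellipse(pts, ax)
    ev = ord_res.explained_variance
    ax.set_xlabel(f"PC1 ({ev.iloc[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev.iloc[1]:.1f}%)" if len(ev) > 1 else "PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "pca_biplot.png", dpi=120)
    plt.close(fig)

    # ENC-GC3 scatter with Wright's curve
    if not points_df.empty:
        fig, ax = plt.subplots(figsize=(7, 5))
        xs = np.linspace(0.0, 1.0, 201)
        ax.plot(xs, enc_expected(xs), "k-", lw=1.5, label="neutral expectation")
        for comp, sub in points_df.groupby("compartment"):
            ax.scatter(sub["gc3s"], sub["enc"], s=8, alpha=0.5, label=comp)
        ax.set_xlabel("GC3s")
        ax.set_ylabel("ENC")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "enc_gc3.png", dpi=120)
        plt.close(fig)


def _confidence_ellipse(pts, ax, n_std: float = 2.4477):
    """95% normal-theory ellipse (sqrt of chi2_2 0.95 quantile ~ 2.4477)."""
    import numpy as np
    from matplotlib.patches import Ellipse

    cov = np.cov(pts.T)
    mean = pts.mean(axis=0)
    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    width, height = 2 * n_std * np.sqrt(np.maximum(vals[::-1], 0))
    ax.add_patch(
        Ellipse(mean, width, height, angle=angle, fill=False, ls="--", lw=1)
    )


def write_report(bundle: OutputBundle) -> str:
    """Plain-text per-order summary: mean ENC +/- SD per compartment, the
    species x gene CAI matrix layout, and coadaptation class counts."""
    lines = ["# mitocodon run summary", ""]
    sm = bundle.species_metrics
    if not sm.empty:
        lines.append("## Mean ENC per order (species-level concatenations)")
        for comp in ("mito", "nuclear"):
            sub = sm[sm["compartment"] == comp]
            if sub.empty:
                continue
            lines.append(f"  [{comp}]")
            agg = sub.groupby("order_label")["enc"].agg(["mean", "std", "count"])
            for order, row in agg.iterrows():
                sd = 0.0 if math.isnan(row["std"]) else row["std"]
                lines.append(
                    f"    {order:<20s} {row['mean']:6.2f} +/- {sd:5.2f}"
                    f"  (n={int(row['count'])})"
                )
        lines.append("")
    if not bundle.cai_matrix.empty:
        lines.append("## Per-gene CAI, order means (13 canonical PCGs)")
        merged = bundle.cai_matrix.copy()
        lines.append("    " + " ".join(f"{g:>6s}" for g in CANONICAL_MITO_GENES))
        lines.append(
            "    " + " ".join(
                f"{merged[g].mean():6.3f}" if g in merged and merged[g].notna().any()
                else "    NA"
                for g in CANONICAL_MITO_GENES
            )
        )
        lines.append("")
    if not bundle.coadaptation.empty:
        lines.append("## Mitonuclear coadaptation classes")
        for cls, n in bundle.coadaptation["class"].value_counts().items():
            lines.append(f"    {cls:<14s} {n}")
        lines.append("")
    if bundle.neutrality:
        lines.append("## Neutrality regression (GC12 ~ GC3)")
        for comp, fit in bundle.neutrality.items():
            if isinstance(fit, dict):
                lines.append(
                    f"    {comp}: slope {fit['slope']:.3f} "
                    f"[{fit['slope_ci_low']:.3f}, {fit['slope_ci_high']:.3f}], "
                    f"R^2 {fit['r_squared']:.3f}"
                )
    text = "\n".join(lines) + "\n"
    (bundle.outdir / "report.txt").write_text(text)
    return text
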