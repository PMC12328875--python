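"""Stage orchestration for the end-to-end analysis.

Stages communicate through plain text artifacts under a run directory::

    cohort/            simulated inputs (VCFs, FASTA, TSVs, truth.json)
    peptides.tsv       enumerated mutant/wildtype windows
    predictions.tsv    per-(patient, peptide, allele) binding predictions
    neoantigens.tsv    classified unique neoantigens with quality scores
    features.tsv       per-patient feature panel
    survival_results.tsv   per-biomarker Cox table (univariate + adjusted)
    riskmodel_results.tsv  per-model AUC / Youden cutoffs
    report.md          human-readable summary
    manifest.json      config snapshot, seed, checksums, timings

Each stage validates that its upstream artifacts exist and names the stage
to run when they do not.  Per-stage counters (variants read, missense kept,
peptides enumerated, neoantigens passing) are logged and recorded in the
manifest so cohort summaries are one grep away.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    PeptideSet,
    build_self_peptidome,
    recognition_scores_many,
)
from .binding import (
    MockBindingPredictor,
    TableBindingPredictor,
    build_neoantigen_records,
)
from .features import (
    build_feature_table,
    compute_patient_features,
    write_feature_table,
)
from .io import (
    read_annotated_vcf,
    read_binding_table,
    read_clinical,
    read_hla_typing,
    read_proteome_fasta,
    read_tcr_table,
)
from .peptides import enumerate_peptide_pairs
from .riskmodel import RelapseRiskModel, compare_auc, roc_analysis
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .survival import CoxPHModel, km_estimate, optimal_cutoff

logger = logging.getLogger(__name__)

STAGES = ["simulate", "enumerate", "predict", "features", "survival",
          "riskmodel", "report"]

#: Table-2-style biomarkers and the unit each hazard ratio is reported per
BIOMARKER_UNITS: Dict[str, float] = {
    "nssnv_load": 100, "hvsnv_load": 100, "neoantigen_load": 1000,
    "neoantigen_frequency": 1, "n_ic500": 100, "n_ic50": 10, "n_ic34": 1,
    "n_el2": 1000, "n_el05": 100, "n_dai10": 10, "n_dissim075": 1,
    "n_iedb09": 100, "promiscuity_count": 100, "driver_count": 1,
}

RISK_FEATURES = ["neoantigen_load", "neoantigen_frequency", "n_dai10",
                 "promiscuity_count"]


class MissingArtifactError(FileNotFoundError):
    pass


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"{path.name} not found; run the '{stage}' stage first"
        )
    return path


def load_config(path: Optional[str]) -> dict:
    if path is None:
        with resources.files("neoquant.data").joinpath("demo_config.yaml").open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def bundled_epitopes() -> List[str]:
    """The bundled synthetic epitope set (stand-in for a curated database)."""
    from Bio import SeqIO

    with resources.files("neoquant.data").joinpath(
        "synthetic_epitopes.fasta"
    ).open() as fh:
        return [str(r.seq) for r in SeqIO.parse(fh, "fasta")]


class Manifest:
    def __init__(self, outdir: Path, config: dict, seed: Optional[int]):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}, "outputs": {},
                         "counters": {}}
        self.data["config"] = config
        self.data["seed"] = seed

    def record(self, stage: str, seconds: float, outputs: Sequence[Path],
               counters: Optional[dict] = None) -> None:
        self.data["stages"][stage] = {"seconds": round(seconds, 3)}
        for p in outputs:
            self.data["outputs"][p.name] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
        if counters:
            self.data["counters"].setdefault(stage, {}).update(counters)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _make_predictor(cfg: dict, seed: int):
    spec = cfg.get("predictor", "mock")
    if spec == "mock":
        return MockBindingPredictor(
            seed=seed,
            strong_binder_frac=cfg.get("strong_binder_frac", 0.013),
            ic50_binder_frac=cfg.get("ic50_binder_frac", 0.013),
            allele_share=cfg.get("allele_share", 0.65),
            arm_corr=cfg.get("arm_corr", 0.7),
        )
    if str(spec).startswith("table:"):
        table = read_binding_table(str(spec)[6:], cfg.get("dialect", "canonical"))
        return TableBindingPredictor(table)
    raise ValueError(f"unknown predictor spec {spec!r}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, outdir: Path, seed: Optional[int],
                   manifest: Manifest) -> None:
    t0 = time.time()
    sim_cfg = SimulationConfig.from_dict(config.get("simulate", {}))
    if seed is not None:
        sim_cfg.seed = seed
    cohort = simulate_cohort(sim_cfg)
    files = write_cohort(cohort, outdir / "cohort")
    n_var = sum(len(v) for v in cohort.variants.values())
    logger.info("simulate: %d patients, %d variants", sim_cfg.n_patients, n_var)
    manifest.record(
        "simulate", time.time() - t0,
        [p for k, p in files.items() if not k.startswith("vcf:")],
        {"patients": sim_cfg.n_patients, "variants": n_var},
    )


def stage_enumerate(config: dict, outdir: Path, manifest: Manifest) -> None:
    t0 = time.time()
    cohort_dir = _need(outdir / "cohort", "simulate")
    proteome = read_proteome_fasta(_need(cohort_dir / "proteome.fasta", "simulate"))
    vcf_dir = _need(cohort_dir / "vcf", "simulate")
    rows = []
    n_variants = 0
    for vcf in sorted(vcf_dir.glob("*.vcf")):
        pid = vcf.stem
        variants = read_annotated_vcf(vcf, pid)
        n_variants += len(variants)
        for v in variants:
            for pair in enumerate_peptide_pairs(v, proteome):
                rows.append(
                    (pid, v.gene, v.protein_position, v.ref_aa, v.alt_aa,
                     pair.length, pair.offset, pair.mutant_seq,
                     pair.wildtype_seq)
                )
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "gene", "protein_position", "ref_aa", "alt_aa",
                 "length", "offset", "mutant_seq", "wildtype_seq"],
    )
    out = outdir / "peptides.tsv"
    df.to_csv(out, sep="\t", index=False)
    logger.info("enumerate: %d variants -> %d peptide pairs", n_variants, len(df))
    manifest.record("enumerate", time.time() - t0, [out],
                    {"variants_read": n_variants, "peptide_pairs": len(df)})


def stage_predict(config: dict, outdir: Path, seed: Optional[int],
                  manifest: Manifest) -> None:
    t0 = time.time()
    peptides = pd.read_csv(_need(outdir / "peptides.tsv", "enumerate"), sep="\t")
    hla = read_hla_typing(_need(outdir / "cohort" / "hla.tsv", "simulate"))
    predictor = _make_predictor(config.get("predict", {}), seed or 0)
    rows = []
    for pid, grp in peptides.groupby("patient_id"):
        alleles = hla[pid].alleles
        peps = pd.unique(
            pd.concat([grp["mutant_seq"], grp["wildtype_seq"]], ignore_index=True)
        )
        for pep in peps:
            for al in alleles:
                try:
                    ic50, el = predictor.predict(pep, al)
                except KeyError:
                    continue
                rows.append((pid, pep, al.name, ic50, el))
    df = pd.DataFrame(
        rows, columns=["patient_id", "peptide", "allele", "ic50_nm",
                       "el_rank_pct"],
    )
    out = outdir / "predictions.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.5g")
    logger.info("predict: %d predictions", len(df))
    manifest.record("predict", time.time() - t0, [out],
                    {"predictions": len(df)})


def stage_features(config: dict, outdir: Path, manifest: Manifest) -> None:
    t0 = time.time()
    fcfg = config.get("features", {})
    cohort_dir = _need(outdir / "cohort", "simulate")
    proteome = read_proteome_fasta(cohort_dir / "proteome.fasta")
    hla = read_hla_typing(cohort_dir / "hla.tsv")
    tcr = read_tcr_table(cohort_dir / "tcr.tsv")
    onc_path = cohort_dir / "oncogenes.txt"
    oncogenes = set(onc_path.read_text().split()) if onc_path.exists() else set()
    preds = pd.read_csv(_need(outdir / "predictions.tsv", "predict"), sep="\t")
    score_quality = fcfg.get("score_quality", True)
    epitopes = PeptideSet(bundled_epitopes()) if score_quality else []

    vectors = []
    neo_rows = []
    provenance: Dict[str, Dict[str, list]] = {}
    n_neo_total = 0
    for vcf in sorted((cohort_dir / "vcf").glob("*.vcf")):
        pid = vcf.stem
        variants = read_annotated_vcf(vcf, pid)
        pairs = []
        for v in variants:
            pairs.extend(enumerate_peptide_pairs(v, proteome))
        ppred = preds[preds["patient_id"] == pid]
        predictor = TableBindingPredictor(
            ppred.rename(columns={})[["peptide", "allele", "ic50_nm",
                                      "el_rank_pct"]]
        )
        records = build_neoantigen_records(pairs, hla[pid].alleles, predictor)
        if score_quality and records:
            mutated_genes = sorted({v.gene for v in variants})
            self_pep = PeptideSet(build_self_peptidome(proteome, mutated_genes))
            peps = [rec.peptide for rec in records]
            iedb = recognition_scores_many(peps, epitopes)
            dissim = 1.0 - recognition_scores_many(peps, self_pep)
            for rec, ie, di in zip(records, iedb, dissim):
                rec.iedb_score = float(ie)
                rec.dissimilarity = float(di)
        provenance[pid] = {
            rec.peptide: [f"{v.gene}:{v.protein_position}:{v.ref_aa}>{v.alt_aa}"
                          for v in rec.source_variants]
            for rec in records
        }
        for rec in records:
            rec.oncogene_flag = bool(set(rec.genes) & oncogenes)
            neo_rows.append(
                (pid, rec.peptide, ";".join(a.name for a in rec.binding_alleles),
                 rec.best_ic50, rec.best_el_rank, rec.dai, rec.iedb_score,
                 rec.dissimilarity, int(rec.oncogene_flag),
                 ";".join(f"{v.gene}:{v.protein_position}"
                          for v in rec.source_variants))
            )
        n_neo_total += len(records)
        vectors.append(
            compute_patient_features(
                pid, variants, records, oncogenes,
                exome_mb=fcfg.get("exome_mb", 34.0),
                frequency_denominator=fcfg.get("frequency_denominator", "hvsnv"),
                tcr_counts=tcr.get(pid),
            )
        )
        logger.info("features[%s]: %d variants, %d pairs, %d neoantigens",
                    pid, len(variants), len(pairs), len(records))
    table = build_feature_table(vectors)
    feat_out = outdir / "features.tsv"
    write_feature_table(table, feat_out)
    neo_out = outdir / "neoantigens.tsv"
    pd.DataFrame(
        neo_rows,
        columns=["patient_id", "peptide", "binding_alleles", "best_ic50",
                 "best_el_rank", "dai", "iedb_score", "dissimilarity",
                 "oncogene_flag", "source_variants"],
    ).to_csv(neo_out, sep="\t", index=False, float_format="%.5g")
    prov_out = outdir / "provenance.json"
    prov_out.write_text(json.dumps(provenance, indent=1, sort_keys=True))
    manifest.record("features", time.time() - t0,
                    [feat_out, neo_out, prov_out],
                    {"neoantigens_passing": n_neo_total})


def _clinical_frame(cohort_dir: Path) -> pd.DataFrame:
    clin = read_clinical(cohort_dir / "clinical.tsv")
    rows = []
    for pid, r in clin.items():
        rows.append({
            "patient_id": pid, "ttr_time": r.ttr_time,
            "ttr_event": int(r.ttr_event), "rfs_time": r.rfs_time,
            "rfs_event": int(r.rfs_event), "sex": r.sex, "stage": r.stage,
            "smoking": int(r.smoking), "histology": r.histology,
            "egfr": int(r.egfr), "kras": int(r.kras),
        })
    return pd.DataFrame(rows).set_index("patient_id")


def _adjustment_columns(df: pd.DataFrame) -> List[str]:
    df["sex_F"] = (df["sex"] == "F").astype(float)
    df["hist_SCC"] = (df["histology"] == "SCC").astype(float)
    df["stage_II"] = (df["stage"] == "II").astype(float)
    df["stage_III"] = (df["stage"] == "III").astype(float)
    cand = ["sex_F", "hist_SCC", "stage_II", "stage_III", "smoking", "egfr",
            "kras"]
    return [c for c in cand if df[c].astype(float).nunique() > 1]


def stage_survival(config: dict, outdir: Path, manifest: Manifest) -> None:
    t0 = time.time()
    features = pd.read_csv(_need(outdir / "features.tsv", "features"),
                           sep="\t").set_index("patient_id")
    df = features.join(_clinical_frame(_need(outdir / "cohort", "simulate")))
    adj = _adjustment_columns(df)
    rows = []
    for endpoint in ("ttr", "rfs"):
        dur, ev = f"{endpoint}_time", f"{endpoint}_event"
        for marker, unit in BIOMARKER_UNITS.items():
            if marker not in df.columns or df[marker].nunique() <= 1:
                continue
            row = {"endpoint": endpoint.upper(), "variable": marker,
                   "per_unit": unit}
            for label, covs in (("uni", [marker]), ("adj", [marker] + adj)):
                try:
                    res = CoxPHModel(
                        df, dur, ev, covs, unit_scales={marker: unit}
                    ).fit()
                    ci = res.conf_int[0]
                    row.update({
                        f"{label}_HR": res.hazard_ratios[0],
                        f"{label}_lower95": ci[0], f"{label}_upper95": ci[1],
                        f"{label}_p": res.p_values[0],
                    })
                except Exception as exc:  # small cohorts may not converge
                    logger.warning("Cox %s/%s (%s) failed: %s", endpoint,
                                   marker, label, exc)
                    row.update({f"{label}_HR": np.nan})
            try:
                cut = optimal_cutoff(df[marker], df[dur], df[ev])
                row["cutoff"] = cut.cutoff
                row["cutoff_logrank_p"] = cut.p_value
            except ValueError:
                pass
            rows.append(row)
    out = outdir / "survival_results.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.4g")

    # KM curves: cohort-wide and high/low at the optimal cutoff for the
    # headline markers, in long format for plotting
    km_rows = []
    for endpoint in ("ttr", "rfs"):
        dur, ev = f"{endpoint}_time", f"{endpoint}_event"
        curves = {"all": df}
        for marker in ("nssnv_load", "neoantigen_load",
                       "neoantigen_frequency"):
            try:
                cut = optimal_cutoff(df[marker], df[dur], df[ev])
            except ValueError:
                continue
            hi = df[marker] > cut.cutoff
            curves[f"{marker}_high"] = df[hi]
            curves[f"{marker}_low"] = df[~hi]
        for name, sub in curves.items():
            if not sub[ev].astype(bool).any():
                continue
            km = km_estimate(sub[dur], sub[ev].astype(bool))
            for t, s, r in zip(km.timeline, km.survival, km.at_risk):
                km_rows.append((endpoint.upper(), name, t, s, r))
    km_out = outdir / "km_curves.tsv"
    pd.DataFrame(
        km_rows, columns=["endpoint", "group", "time", "survival", "at_risk"]
    ).to_csv(km_out, sep="\t", index=False, float_format="%.6g")
    manifest.record("survival", time.time() - t0, [out, km_out],
                    {"biomarkers": len(rows) // 2})


def stage_riskmodel(config: dict, outdir: Path, manifest: Manifest) -> None:
    t0 = time.time()
    rcfg = config.get("riskmodel", {})
    horizon = rcfg.get("horizon_months", 36.0)
    feature_list = rcfg.get("features", RISK_FEATURES)
    features = pd.read_csv(_need(outdir / "features.tsv", "features"),
                           sep="\t").set_index("patient_id")
    clinical = _clinical_frame(_need(outdir / "cohort", "simulate"))
    rows = []
    rocs = {}
    coefs = {}
    model_specs = [(f, [f]) for f in feature_list if
                   features[f].nunique() > 1]
    if len(model_specs) > 1:
        model_specs.append(("combined", [f for f, _ in model_specs]))
    for name, feats in model_specs:
        try:
            model = RelapseRiskModel(features, clinical, feats, horizon=horizon)
            res = model.fit()
            probs = res.predict_probability(model.transformed_design())
            roc = roc_analysis(probs, model.outcome.to_numpy())
            rocs[name] = roc
            coefs[name] = {k: float(v) for k, v in res.params.items()}
            rows.append({
                "model": name, "n": model.n, "auc": roc.auc,
                "youden_j": roc.youden_j, "youden_cutoff": roc.youden_cutoff,
                "separation_flag": res.separation_flag,
            })
        except Exception as exc:
            logger.warning("risk model %s failed: %s", name, exc)
            rows.append({"model": name, "auc": np.nan})
    if "combined" in rocs and len(rocs) > 1:
        base = next(n for n in rocs if n != "combined")
        z, p = compare_auc(rocs["combined"], rocs[base])
        rows.append({"model": f"combined_vs_{base}", "auc": np.nan,
                     "youden_j": np.nan, "compare_p": p})
    out = outdir / "riskmodel_results.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.4g")
    coef_out = outdir / "riskmodel_coefficients.json"
    coef_out.write_text(json.dumps(coefs, indent=1, sort_keys=True))
    manifest.record("riskmodel", time.time() - t0, [out, coef_out],
                    {"models": len(rocs)})


def stage_report(config: dict, outdir: Path, manifest: Manifest) -> None:
    t0 = time.time()
    feats = pd.read_csv(_need(outdir / "features.tsv", "features"), sep="\t")
    surv = pd.read_csv(_need(outdir / "survival_results.tsv", "survival"),
                       sep="\t")
    risk = pd.read_csv(_need(outdir / "riskmodel_results.tsv", "riskmodel"),
                       sep="\t")
    lines = ["# neoquant run report", ""]
    lines.append(f"Patients: {len(feats)}")
    for col in ("nssnv_load", "hvsnv_load", "neoantigen_load",
                "neoantigen_frequency"):
        med = feats[col].median()
        lines.append(f"- median {col}: {med:.4g}")
    lines += ["", "## Survival models (per-biomarker Cox)", "",
              surv.to_markdown(index=False), "",
              "## Relapse risk models (3-year relapse-free)", "",
              risk.to_markdown(index=False), ""]
    out = outdir / "report.md"
    out.write_text("\n".join(lines))
    manifest.record("report", time.time() - t0, [out])


def run(stage: str, config: dict, outdir: str | Path,
        seed: Optional[int] = None) -> Path:
    """Run one stage (or ``all``) into ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config, seed)
    stages = STAGES if stage == "all" else [stage]
    for st in stages:
        if st == "simulate":
            stage_simulate(config, outdir, seed, manifest)
        elif st == "enumerate":
            stage_enumerate(config, outdir, manifest)
        elif st == "predict":
            stage_predict(config, outdir, seed, manifest)
        elif st == "features":
            stage_features(config, outdir, manifest)
        elif st == "survival":
            stage_survival(config, outdir, manifest)
        elif st == "riskmodel":
            stage_riskmodel(config, outdir, manifest)
        elif st == "report":
            stage_report(config, outdir, manifest)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    return outdir
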