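"""Per-patient neoantigen feature panel.

Aggregates a patient's variants and neoantigen records into the quantities
analysed downstream: nsSNV load, hvSNV load (mutations yielding at least one
neoantigen), neoantigen load (unique passing peptides), neoantigen frequency
(neoantigens per hvSNV by default), threshold counts on the IC50/EL arms,
quality counts (DAI >= 10, dissimilarity >= 0.75, IEDB >= 0.9), HLA binding
promiscuity, oncogene-derived counts, TMB and TCR repertoire indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binding import NeoantigenRecord
from .io import SomaticVariant
from .tcr import inverse_simpson, simpson_clonality

DEFAULT_EXOME_MB = 34.0

DAI_CUT = 10.0
DISSIM_CUT = 0.75
IEDB_CUT = 0.9


@dataclass
class PatientFeatureVector:
    patient_id: str
    nssnv_load: int = 0
    hvsnv_load: int = 0
    neoantigen_load: int = 0
    neoantigen_frequency: float = 0.0
    n_el2: int = 0
    n_el05: int = 0
    n_ic500: int = 0
    n_ic50: int = 0
    n_ic34: int = 0
    n_dai10: int = 0
    n_dissim075: int = 0
    n_iedb09: int = 0
    promiscuity_count: int = 0
    promiscuity_fraction: float = 0.0
    cross_gene_fraction: float = 0.0
    cross_group_fraction: float = 0.0
    driver_count: int = 0
    tmb: float = 0.0
    tcr_diversity: Optional[float] = None
    tcr_clonality: Optional[float] = None

    def to_dict(self) -> Dict[str, object]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def classify_promiscuity(record: NeoantigenRecord) -> Tuple[str, Optional[str]]:
    """Promiscuity class of one neoantigen.

    Returns ``("monoallelic", None)`` for single-allele binders, otherwise
    ``("promiscuous", scope)`` with scope ``cross-gene`` (alleles span >= 2
    HLA genes), ``cross-group`` (one gene, >= 2 allele groups) or
    ``within-group``.
    """
    alleles = record.binding_alleles
    if not alleles:
        raise ValueError("record has no binding alleles")
    if len(set(alleles)) < 2:
        return "monoallelic", None
    genes = {a.gene for a in alleles}
    if len(genes) >= 2:
        return "promiscuous", "cross-gene"
    groups = {(a.gene, a.allele_group) for a in alleles}
    if len(groups) >= 2:
        return "promiscuous", "cross-group"
    return "promiscuous", "within-group"


def compute_patient_features(
    patient_id: str,
    variants: Sequence[SomaticVariant],
    records: Sequence[NeoantigenRecord],
    oncogene_list: Iterable[str] = (),
    exome_mb: float = DEFAULT_EXOME_MB,
    frequency_denominator: str = "hvsnv",
    tcr_counts=None,
) -> PatientFeatureVector:
    """Aggregate one patient's variants and neoantigen records.

    ``frequency_denominator`` selects neoantigens-per-hvSNV (default; the
    scale on which the reference cohort's median of 6.4 lives) or
    per-nsSNV.
    """
    variant_keys = {v.key for v in variants}
    for rec in records:
        for v in rec.source_variants:
            if v.key not in variant_keys:
                raise ValueError(
                    f"record {rec.peptide} references unknown variant {v.key}"
                )
    oncogenes = set(oncogene_list)

    hv_variants = set()
    for rec in records:
        for v in rec.source_variants:
            hv_variants.add(v.key)

    load = len({r.peptide for r in records})
    if len(records) != load:
        raise ValueError("duplicate peptide sequences among records")

    fv = PatientFeatureVector(patient_id=patient_id)
    fv.nssnv_load = len(variant_keys)
    fv.hvsnv_load = len(hv_variants)
    fv.neoantigen_load = load
    denom = fv.hvsnv_load if frequency_denominator == "hvsnv" else fv.nssnv_load
    fv.neoantigen_frequency = load / denom if denom else 0.0
    fv.tmb = fv.nssnv_load / exome_mb if exome_mb > 0 else 0.0

    n_prom = n_cross_gene = n_cross_group = 0
    for rec in records:
        if rec.passes_el:
            fv.n_el2 += 1
        if rec.passes_ic50:
            fv.n_ic500 += 1
        if rec.el_le_05:
            fv.n_el05 += 1
        if rec.ic50_le_50:
            fv.n_ic50 += 1
        if rec.ic50_lt_34:
            fv.n_ic34 += 1
        if rec.dai is not None and rec.dai >= DAI_CUT:
            fv.n_dai10 += 1
        if rec.dissimilarity is not None and rec.dissimilarity >= DISSIM_CUT:
            fv.n_dissim075 += 1
        if rec.iedb_score is not None and rec.iedb_score >= IEDB_CUT:
            fv.n_iedb09 += 1
        if rec.oncogene_flag or (oncogenes and set(rec.genes) & oncogenes):
            fv.driver_count += 1
        kind, scope = classify_promiscuity(rec)
        if kind == "promiscuous":
            n_prom += 1
            if scope == "cross-gene":
                n_cross_gene += 1
            elif scope == "cross-group":
                n_cross_group += 1
    fv.promiscuity_count = n_prom
    fv.promiscuity_fraction = n_prom / load if load else 0.0
    fv.cross_gene_fraction = n_cross_gene / n_prom if n_prom else 0.0
    fv.cross_group_fraction = n_cross_group / n_prom if n_prom else 0.0

    if tcr_counts is not None and len(tcr_counts):
        fv.tcr_diversity = inverse_simpson(tcr_counts)
        fv.tcr_clonality = simpson_clonality(tcr_counts)
    return fv


FEATURE_COLUMNS = [f.name for f in dc_fields(PatientFeatureVector)]


def build_feature_table(
    feature_vectors: Sequence[PatientFeatureVector],
) -> pd.DataFrame:
    """Stack per-patient vectors into the patients x features table with a
    stable column order.  Duplicate patient ids are an error; missing TCR
    metrics stay null."""
    ids = [fv.patient_id for fv in feature_vectors]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    df = pd.DataFrame([fv.to_dict() for fv in feature_vectors],
                      columns=FEATURE_COLUMNS)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
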