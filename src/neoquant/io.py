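"""Readers and validators for the pipeline's standard inputs.

Inputs are the files a variant-annotation workflow leaves behind: per-patient
SnpEff-annotated VCFs (missense calls with ``ANN`` INFO fields), a reference
proteome FASTA, HLA class-I typings, a clinical outcome table, TCR clone-count
tables, and optional external peptide-MHC binding prediction tables
(canonical TSV or netMHCpan-4.1-style output).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import IUPACData

logger = logging.getLogger(__name__)

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

_3TO1 = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}


class FormatError(ValueError):
    """An input file violates its documented format."""


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated non-synonymous SNV (amino-acid level)."""

    patient_id: str
    gene: str
    protein_position: int  # 1-based
    ref_aa: str
    alt_aa: str
    transcript: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"synonymous change {self.ref_aa}->{self.alt_aa}")
        if self.protein_position < 1:
            raise ValueError("protein_position is 1-based and must be >= 1")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.gene, self.protein_position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A two-field HLA class-I allele, e.g. HLA-A*02:01."""

    gene: str  # A, B or C
    allele_group: str  # 2-digit field, "02"
    protein: str  # 2-digit field, "01"

    @property
    def name(self) -> str:
        return f"HLA-{self.gene}*{self.allele_group}:{self.protein}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.name


_HLA_RE = re.compile(r"^(?:HLA-)?([A-Z]+[0-9]*)\*?(\d{2,3}):(\d{2,3})")


def parse_hla_allele(name: str) -> HLAAllele:
    """Parse an ``HLA-A*02:01``-style allele name (``HLA-`` prefix optional)."""
    if not name or not name.strip():
        raise FormatError("empty HLA allele name")
    m = _HLA_RE.match(name.strip())
    if m is None:
        raise FormatError(f"malformed HLA allele name: {name!r}")
    gene, group, protein = m.groups()
    if gene not in {"A", "B", "C"}:
        raise FormatError(f"unsupported HLA gene {gene!r} in {name!r}")
    return HLAAllele(gene=gene, allele_group=group, protein=protein)


@dataclass
class SurvivalRecord:
    """Recurrence and survival endpoints plus clinical covariates.

    ``ttr`` is time to recurrence (censored at death or last follow-up);
    ``rfs`` is recurrence-free survival (recurrence or death, whichever
    occurs first).  Times are months since surgical resection.
    """

    patient_id: str
    ttr_time: float
    ttr_event: bool
    rfs_time: float
    rfs_event: bool
    sex: str = "M"  # M / F
    stage: str = "I"  # I / II / III
    smoking: bool = True
    histology: str = "ADC"  # ADC / SCC
    egfr: bool = False
    kras: bool = False

    def validate(self) -> None:
        if self.ttr_time < 0 or self.rfs_time < 0:
            raise FormatError(f"{self.patient_id}: negative follow-up time")
        if self.rfs_time - self.ttr_time > 1e-9:
            raise FormatError(
                f"{self.patient_id}: rfs_time exceeds ttr_time "
                "(RFS ends at the earliest of recurrence, death, follow-up)"
            )
        if self.stage not in {"I", "II", "III"}:
            raise FormatError(f"{self.patient_id}: bad stage {self.stage!r}")
        if self.sex not in {"M", "F"}:
            raise FormatError(f"{self.patient_id}: bad sex {self.sex!r}")


@dataclass
class HLATyping:
    """A patient's deduplicated class-I allele list with zygosity metadata."""

    patient_id: str
    alleles: List[HLAAllele]
    n_listed: int = field(default=0)

    @property
    def homozygous(self) -> bool:
        return len(self.alleles) < self.n_listed or len(self.alleles) < 6


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_HGVSP_RE = re.compile(r"p\.(?:\()?([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])")


def _aa1(code: str) -> Optional[str]:
    if len(code) == 1:
        return code if code in VALID_AA else None
    return _3TO1.get(code.upper())


def parse_hgvs_p(hgvs: str) -> Optional[Tuple[str, int, str]]:
    """Extract (ref_aa, position, alt_aa) from an HGVS.p missense string."""
    m = _HGVSP_RE.search(hgvs)
    if m is None:
        return None
    ref3, pos, alt3 = m.groups()
    ref, alt = _aa1(ref3), _aa1(alt3)
    if ref is None or alt is None:
        return None
    return ref, int(pos), alt


def read_annotated_vcf(path: str | Path, patient_id: str) -> List[SomaticVariant]:
    """Read missense variants from a SnpEff ``ANN``-annotated VCF.

    Keeps only ``missense_variant`` annotations; for multi-transcript
    annotations the first missense entry (SnpEff's canonical-first ordering)
    is used.  Multi-allelic sites are handled per ALT allele; duplicate
    (locus, alt) records are collapsed.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: List[SomaticVariant] = []
    seen_loci = set()
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            ann = rec.INFO.get("ANN")
            if ann is None:
                raise FormatError(
                    f"{path.name}: record {rec.CHROM}:{rec.POS} lacks INFO/ANN"
                )
            for alt in rec.ALT:
                locus = (rec.CHROM, rec.POS, rec.REF, alt)
                if locus in seen_loci:
                    continue
                for entry in ann.split(","):
                    f = entry.split("|")
                    if len(f) < 11:
                        continue
                    if f[0] != alt or "missense_variant" not in f[1]:
                        continue
                    parsed = parse_hgvs_p(f[10])
                    if parsed is None:
                        logger.warning(
                            "%s: unparseable HGVS.p %r at %s:%s; record skipped",
                            path.name, f[10], rec.CHROM, rec.POS,
                        )
                        continue
                    ref_aa, ppos, alt_aa = parsed
                    if ref_aa == alt_aa:
                        continue
                    out.append(
                        SomaticVariant(
                            patient_id=patient_id,
                            gene=f[3],
                            transcript=f[6] or None,
                            protein_position=ppos,
                            ref_aa=ref_aa,
                            alt_aa=alt_aa,
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=rec.REF,
                            alt=alt,
                        )
                    )
                    seen_loci.add(locus)
                    break  # first missense annotation only
    finally:
        vcf.close()
    return out


# ---------------------------------------------------------------------------
# FASTA / tables
# ---------------------------------------------------------------------------

def read_proteome_fasta(path: str | Path) -> Dict[str, str]:
    """Read a proteome FASTA into a gene -> uppercase AA sequence map.

    Header word before the first whitespace is taken as the gene symbol.
    Non-canonical residues are masked to ``X`` with a warning.
    """
    path = Path(path)
    proteome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_AA - {"X"}
        if bad:
            warnings.warn(
                f"{rec.id}: non-canonical residues {sorted(bad)} masked to X"
            )
            seq = "".join(c if c in VALID_AA else "X" for c in seq)
        proteome[rec.id] = seq
    if not proteome:
        raise FormatError(f"empty FASTA: {path}")
    return proteome


def read_hla_typing(path: str | Path) -> Dict[str, HLATyping]:
    """Read ``hla.tsv`` (patient_id, comma-separated alleles)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["patient_id", "alleles"], path)
    out: Dict[str, HLATyping] = {}
    for _, row in df.iterrows():
        names = [a for a in re.split(r"[,;]\s*", row["alleles"].strip()) if a]
        alleles: List[HLAAllele] = []
        for n in names:
            al = parse_hla_allele(n)
            if al not in alleles:
                alleles.append(al)
        out[row["patient_id"]] = HLATyping(
            patient_id=row["patient_id"], alleles=alleles, n_listed=len(names)
        )
    return out


_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False, "mutant": True, "wt": False,
         "wildtype": False, "ever": True, "never": False}


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _BOOL:
        return _BOOL[s]
    raise FormatError(f"cannot interpret {v!r} as a yes/no flag")


def read_clinical(path: str | Path) -> Dict[str, SurvivalRecord]:
    """Read ``clinical.tsv`` into validated per-patient survival records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = ["patient_id", "ttr_time", "ttr_event", "rfs_time", "rfs_event",
            "sex", "stage", "smoking", "histology", "egfr", "kras"]
    _require(df, cols, path)
    out: Dict[str, SurvivalRecord] = {}
    for _, row in df.iterrows():
        rec = SurvivalRecord(
            patient_id=row["patient_id"],
            ttr_time=float(row["ttr_time"]),
            ttr_event=_as_bool(row["ttr_event"]),
            rfs_time=float(row["rfs_time"]),
            rfs_event=_as_bool(row["rfs_event"]),
            sex=row["sex"],
            stage=row["stage"],
            smoking=_as_bool(row["smoking"]),
            histology=row["histology"],
            egfr=_as_bool(row["egfr"]),
            kras=_as_bool(row["kras"]),
        )
        rec.validate()
        if rec.patient_id in out:
            raise FormatError(f"duplicate patient id {rec.patient_id}")
        out[rec.patient_id] = rec
    return out


def read_tcr_table(path: str | Path) -> Dict[str, pd.DataFrame]:
    """Read ``tcr.tsv`` (patient_id, cdr3_aa, templates) grouped by patient."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["patient_id", "cdr3_aa", "templates"], path)
    if (df["templates"] < 1).any():
        raise FormatError(f"{path}: template counts must be positive integers")
    return {pid: g[["cdr3_aa", "templates"]].reset_index(drop=True)
            for pid, g in df.groupby("patient_id")}


# ---------------------------------------------------------------------------
# binding-prediction tables
# ---------------------------------------------------------------------------

def read_binding_table(path: str | Path, dialect: str = "canonical") -> pd.DataFrame:
    """Read external binding predictions into a (peptide, allele) table.

    Returns a DataFrame with columns ``peptide, allele, ic50_nm, el_rank_pct``
    (EL rank in percent units, IC50 in nM).  ``dialect`` is ``canonical``
    (TSV with those headers) or ``netmhcpan`` (netMHCpan-4.1-style
    whitespace table with ``Peptide``, ``MHC``, affinity and ``%Rank``/
    ``EL_Rank`` columns).
    """
    path = Path(path)
    if dialect == "canonical":
        df = pd.read_csv(path, sep="\t")
        _require(df, ["peptide", "allele", "ic50_nm", "el_rank_pct"], path)
        df = df[["peptide", "allele", "ic50_nm", "el_rank_pct"]].copy()
    elif dialect == "netmhcpan":
        df = _read_netmhcpan(path)
    else:
        raise ValueError(f"unknown binding-table dialect {dialect!r}")
    df["allele"] = [parse_hla_allele(a).name for a in df["allele"].astype(str)]
    dup = df.duplicated(subset=["peptide", "allele"], keep=False)
    if dup.any():
        conflicting = (
            df[dup].groupby(["peptide", "allele"])["ic50_nm"].nunique() > 1
        )
        if conflicting.any():
            pairs = list(conflicting[conflicting].index)
            raise FormatError(f"conflicting duplicate predictions for {pairs}")
        df = df.drop_duplicates(subset=["peptide", "allele"])
    if (df["ic50_nm"] <= 0).any() or (df["el_rank_pct"] <= 0).any():
        raise FormatError(f"{path}: predictions must be positive")
    return df.reset_index(drop=True)


def _read_netmhcpan(path: Path) -> pd.DataFrame:
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "---")):
                continue
            fields = line.split()
            if header is None:
                if "Peptide" in fields:
                    header = fields
                continue
            if len(fields) < len(header):
                continue
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise FormatError(f"{path}: no netMHCpan header line with 'Peptide' found")

    def pick(*names):
        for n in names:
            if n in header:
                return n
        raise FormatError(f"{path}: missing any of columns {names}")

    pep_c = pick("Peptide")
    mhc_c = pick("MHC", "HLA", "Allele")
    aff_c = pick("Aff(nM)", "Affinity(nM)", "Aff", "BA_Aff", "ic50")
    rank_c = pick("%Rank_EL", "EL_Rank", "%Rank", "Rank_EL")
    return pd.DataFrame(
        {
            "peptide": [r[pep_c] for r in rows],
            "allele": [r[mhc_c] for r in rows],
            "ic50_nm": [float(r[aff_c]) for r in rows],
            "el_rank_pct": [float(r[rank_c]) for r in rows],
        }
    )


def _require(df: pd.DataFrame, cols: List[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
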