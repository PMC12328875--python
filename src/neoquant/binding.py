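"""Peptide-MHC binding prediction contract, mock landscape, and the
neoantigen classification rule.

A *neoantigen* is a unique mutant peptide passing, on at least one of the
patient's HLA class-I alleles, the dual threshold

    IC50 <= 500 nM   OR   eluted-ligand (EL) percentile rank <= 2.

External predictors (netMHCpan-style tables) and the bundled deterministic
mock both satisfy the same contract: a deterministic map
``(peptide, allele) -> (ic50_nm, el_rank_pct)`` with strictly positive
outputs.

The mock predictor is a pseudo binding landscape, not a trained model: each
allele gets a hashed position-weight matrix per peptide length, a shared
per-peptide propensity couples alleles (producing promiscuous binders), and
the EL rank is the exact upper-tail percentile of the resulting score, so
the fraction of EL binders is controlled analytically.  IC50 is coupled to
the same score through a Gaussian copula so the two arms of the rule overlap
partially, as real predictors do.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .io import HLAAllele, SomaticVariant, parse_hla_allele
from .peptides import PeptidePair

logger = logging.getLogger(__name__)

IC50_CUT = 500.0  # nM
EL_CUT = 2.0  # percent rank


class PredictorContractError(ValueError):
    """A predictor returned values violating the binding contract."""


@dataclass(frozen=True)
class BindingPrediction:
    """One (peptide, allele) prediction: IC50 in nM, EL rank in percent."""

    peptide: str
    allele: HLAAllele
    ic50: float
    el_rank: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ic50) and self.ic50 > 0):
            raise PredictorContractError(f"non-positive IC50 for {self.peptide}")
        if not (math.isfinite(self.el_rank) and 0 < self.el_rank <= 100):
            raise PredictorContractError(
                f"EL rank outside (0, 100] for {self.peptide}"
            )

    def passes(self, ic50_cut: float = IC50_CUT, el_cut: float = EL_CUT) -> bool:
        return self.ic50 <= ic50_cut or self.el_rank <= el_cut


class BindingPredictor(Protocol):
    def predict(self, peptide: str, allele: HLAAllele) -> Tuple[float, float]:
        """Return (ic50_nm, el_rank_pct) for one peptide-allele pair."""
        ...


def _hash_unit(*parts: object) -> float:
    """Deterministic uniform (0,1) from a tuple of values."""
    key = "|".join(str(p) for p in parts).encode()
    h = int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")
    return (h + 0.5) / 2.0**64


class MockBindingPredictor:
    """Deterministic hashed binding landscape satisfying the contract.

    Parameters
    ----------
    seed : int
        Master seed; two mocks with the same seed agree everywhere.
    strong_binder_frac : float
        Marginal probability that a random peptide-allele pair has
        EL rank <= 2 (the EL arm of the neoantigen rule).  0 disables
        binding entirely.
    ic50_binder_frac : float
        Marginal probability of IC50 <= 500 nM at the default
        ``strong_binder_frac``; scaled proportionally when that changes.
    allele_share : float
        Correlation between a peptide's scores on different alleles
        (drives binding promiscuity).
    arm_corr : float
        Gaussian-copula correlation between the EL and IC50 arms.
    """

    def __init__(
        self,
        seed: int = 0,
        strong_binder_frac: float = 0.013,
        ic50_binder_frac: float = 0.013,
        allele_share: float = 0.65,
        arm_corr: float = 0.7,
    ) -> None:
        if not 0 <= strong_binder_frac < 1:
            raise ValueError("strong_binder_frac must be in [0, 1)")
        self.seed = seed
        self.strong_binder_frac = strong_binder_frac
        self.ic50_binder_frac = ic50_binder_frac
        self.allele_share = allele_share
        self.arm_corr = arm_corr
        self._pssms: Dict[Tuple[str, int], np.ndarray] = {}
        self._aa_index = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}

    def _pssm(self, tag: str, length: int) -> np.ndarray:
        key = (tag, length)
        pssm = self._pssms.get(key)
        if pssm is None:
            digest = hashlib.blake2b(
                f"{self.seed}|pssm|{tag}|{length}".encode(), digest_size=4
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            pssm = rng.standard_normal((length, 20))
            self._pssms[key] = pssm
        return pssm

    def _pssm_z(self, tag: str, cols: list) -> float:
        L = len(cols)
        pssm = self._pssm(tag, L)
        return float(pssm[np.arange(L), cols].sum()) / math.sqrt(L)

    def predict(self, peptide: str, allele: HLAAllele) -> Tuple[float, float]:
        """Positional landscape: every score component is a sum of hashed
        per-position residue weights, so a single-residue change (mutant vs
        wildtype window) perturbs rather than re-rolls the score -- most
        mutants bind like their wildtype counterpart and large DAI values
        are the rare anchor-position hits."""
        L = len(peptide)
        if self.strong_binder_frac == 0.0:
            u = _hash_unit(self.seed, "null", peptide, allele.name)
            return 500.0 + 49500.0 * (1 - u), 2.0 + 98.0 * (1 - u)
        try:
            cols = [self._aa_index[aa] for aa in peptide]
        except KeyError as exc:
            raise ValueError(f"invalid residue in peptide {peptide!r}") from exc
        z_allele = self._pssm_z(f"el|{allele.name}", cols)
        z_shared = self._pssm_z("shared", cols)  # allele-independent propensity
        rho = self.allele_share
        z = rho * z_shared + math.sqrt(1 - rho * rho) * z_allele
        u = float(ndtr(z))

        gamma = math.log(0.02) / math.log(self.strong_binder_frac)
        el_rank = float(np.clip(100.0 * (1 - u) ** gamma, 1e-3, 100.0))

        lam = self.arm_corr
        z_noise = self._pssm_z(f"ba|{allele.name}", cols)
        u2 = float(ndtr(lam * z + math.sqrt(1 - lam * lam) * z_noise))
        p_ic = self.ic50_binder_frac * (self.strong_binder_frac / 0.02)
        ic50 = float(np.clip(500.0 * ((1 - u2) / p_ic) ** 1.18, 1.0, 50000.0))
        return ic50, el_rank


class TableBindingPredictor:
    """Predictor backed by an external predictions table.

    ``table`` is the DataFrame produced by
    :func:`neoquant.io.read_binding_table`.  Missing (peptide, allele) pairs
    raise ``KeyError``; classification skips them with a warning.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        self._map: Dict[Tuple[str, str], Tuple[float, float]] = {
            (r.peptide, r.allele): (float(r.ic50_nm), float(r.el_rank_pct))
            for r in table.itertuples()
        }

    def predict(self, peptide: str, allele: HLAAllele) -> Tuple[float, float]:
        try:
            return self._map[(peptide, allele.name)]
        except KeyError:
            raise KeyError(f"no prediction for ({peptide}, {allele.name})")


def predict_binding(
    pairs: Sequence[PeptidePair],
    alleles: Sequence[HLAAllele],
    predictor: BindingPredictor,
    include_wildtype: bool = True,
) -> List[BindingPrediction]:
    """Predictions for every (mutant peptide, allele) pair, and the matched
    wildtype peptides when ``include_wildtype`` (needed for DAI)."""
    peptides: List[str] = []
    seen = set()
    for pair in pairs:
        for seq in (pair.mutant_seq, pair.wildtype_seq) if include_wildtype else (
            pair.mutant_seq,
        ):
            if seq not in seen:
                seen.add(seq)
                peptides.append(seq)
    out: List[BindingPrediction] = []
    for pep in peptides:
        for allele in alleles:
            try:
                ic50, el = predictor.predict(pep, allele)
            except KeyError:
                logger.warning("no prediction for (%s, %s); skipped", pep, allele)
                continue
            out.append(BindingPrediction(pep, allele, ic50, el))
    return out


@dataclass
class NeoantigenRecord:
    """A unique mutant peptide passing the neoantigen rule on >= 1 allele."""

    peptide: str
    source_variants: Tuple[SomaticVariant, ...]
    binding_alleles: Tuple[HLAAllele, ...]
    best_ic50: float
    best_el_rank: float
    passes_ic50: bool  # IC50 arm (<= 500) on some allele
    passes_el: bool  # EL arm (<= 2) on some allele
    dai: Optional[float] = None
    iedb_score: Optional[float] = None
    dissimilarity: Optional[float] = None
    oncogene_flag: bool = False
    # strong-binder sub-flags retained for feature counting
    el_le_05: bool = False
    ic50_le_50: bool = False
    ic50_lt_34: bool = False

    @property
    def genes(self) -> Tuple[str, ...]:
        return tuple(sorted({v.gene for v in self.source_variants}))


def build_neoantigen_records(
    pairs: Sequence[PeptidePair],
    alleles: Sequence[HLAAllele],
    predictor: BindingPredictor,
    ic50_cut: float = IC50_CUT,
    el_cut: float = EL_CUT,
    dai_mode: str = "ratio",
) -> List[NeoantigenRecord]:
    """Classify enumerated peptide pairs into unique neoantigen records.

    Uniqueness is by mutant peptide sequence (across lengths, alleles and
    source variants); per-allele thresholding happens before deduplication.
    DAI is the wildtype:mutant IC50 ratio, maximised over the record's
    binding alleles (``dai_mode="diff"`` gives the difference form instead).
    """
    if dai_mode not in {"ratio", "diff"}:
        raise ValueError("dai_mode must be 'ratio' or 'diff'")
    by_pep: Dict[str, List[PeptidePair]] = {}
    for pair in pairs:
        by_pep.setdefault(pair.mutant_seq, []).append(pair)

    records: List[NeoantigenRecord] = []
    for pep, pep_pairs in by_pep.items():
        preds: Dict[str, BindingPrediction] = {}
        for allele in alleles:
            try:
                ic50, el = predictor.predict(pep, allele)
            except KeyError:
                logger.warning("no prediction for (%s, %s); skipped", pep, allele)
                continue
            preds[allele.name] = BindingPrediction(pep, allele, ic50, el)
        if not preds:
            continue
        passing = [p for p in preds.values() if p.passes(ic50_cut, el_cut)]
        if not passing:
            continue
        best_ic50 = min(p.ic50 for p in preds.values())
        best_el = min(p.el_rank for p in preds.values())

        dai: Optional[float] = None
        for p in passing:
            wt_ic50 = _wildtype_ic50(pep_pairs, p.allele, predictor)
            if wt_ic50 is None:
                continue
            val = wt_ic50 / p.ic50 if dai_mode == "ratio" else wt_ic50 - p.ic50
            dai = val if dai is None else max(dai, val)
        if dai is None:
            logger.warning("no wildtype prediction for %s; DAI unset", pep)

        records.append(
            NeoantigenRecord(
                peptide=pep,
                source_variants=tuple(
                    dict.fromkeys(pair.variant for pair in pep_pairs)
                ),
                binding_alleles=tuple(sorted(p.allele for p in passing)),
                best_ic50=best_ic50,
                best_el_rank=best_el,
                passes_ic50=any(p.ic50 <= ic50_cut for p in passing),
                passes_el=any(p.el_rank <= el_cut for p in passing),
                dai=dai,
                el_le_05=best_el <= 0.5,
                ic50_le_50=best_ic50 <= 50,
                ic50_lt_34=best_ic50 < 34,
            )
        )
    return records


def _wildtype_ic50(
    pep_pairs: Sequence[PeptidePair],
    allele: HLAAllele,
    predictor: BindingPredictor,
) -> Optional[float]:
    vals = []
    for pair in pep_pairs:
        try:
            ic50, _ = predictor.predict(pair.wildtype_seq, allele)
        except KeyError:
            continue
        vals.append(ic50)
    return max(vals) if vals else None


def classify_neoantigens(
    predictions: Sequence[BindingPrediction],
    ic50_cut: float = IC50_CUT,
    el_cut: float = EL_CUT,
) -> List[NeoantigenRecord]:
    """Classification from a flat prediction list (no pair/DAI context).

    Convenience entry point for external prediction tables covering mutant
    peptides only; DAI and source variants are left unset.
    """
    by_pep: Dict[str, List[BindingPrediction]] = {}
    for p in predictions:
        by_pep.setdefault(p.peptide, []).append(p)
    records = []
    for pep, preds in by_pep.items():
        passing = [p for p in preds if p.passes(ic50_cut, el_cut)]
        if not passing:
            continue
        best_ic50 = min(p.ic50 for p in preds)
        best_el = min(p.el_rank for p in preds)
        records.append(
            NeoantigenRecord(
                peptide=pep,
                source_variants=(),
                binding_alleles=tuple(sorted(p.allele for p in passing)),
                best_ic50=best_ic50,
                best_el_rank=best_el,
                passes_ic50=any(p.ic50 <= ic50_cut for p in passing),
                passes_el=any(p.el_rank <= el_cut for p in passing),
                el_le_05=best_el <= 0.5,
                ic50_le_50=best_ic50 <= 50,
                ic50_lt_34=best_ic50 < 34,
            )
        )
    return records


def compute_dai(
    pair: PeptidePair,
    predictor: BindingPredictor,
    alleles: Sequence[HLAAllele],
    mode: str = "ratio",
) -> Optional[float]:
    """DAI of a single peptide pair: wildtype/mutant IC50 on the allele where
    the mutant binds best (minimum mutant IC50)."""
    best_allele, best_mut = None, math.inf
    for allele in alleles:
        try:
            ic50, _ = predictor.predict(pair.mutant_seq, allele)
        except KeyError:
            continue
        if ic50 < best_mut:
            best_mut, best_allele = ic50, allele
    if best_allele is None:
        return None
    try:
        wt_ic50, _ = predictor.predict(pair.wildtype_seq, best_allele)
    except KeyError:
        logger.warning("missing wildtype prediction for %s", pair.wildtype_seq)
        return None
    return wt_ic50 / best_mut if mode == "ratio" else wt_ic50 - best_mut
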