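"""Genotype and animal quality control with a full removal ledger.

The QC chain mirrors routine pre-evaluation cleaning of SNP-chip data:
animals are screened for missingness and parentage consistency
(opposing-homozygote rate against recorded sires, pedigree-vs-genomic
relationship conflicts), then SNPs are filtered in a fixed order —
unknown map position, sex chromosomes, call rate, minor allele frequency,
heterozygosity departure from Hardy-Weinberg expectation — each step
computed on the markers surviving the previous one. Remaining missing
dosages are imputed by the per-SNP mean (2*p_hat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AlignmentError, RelationshipMatrix, ValidationError

#: cattle autosomes; anything else (X, Y, MT, unknown) is non-autosomal
DEFAULT_AUTOSOMES = frozenset(str(c) for c in range(1, 30))

MENDELIAN_RATE_THRESHOLD = 0.02


@dataclass
class GenotypePanel:
    """Animals x SNPs dosage matrix over {0, 1, 2, NaN} with a SNP map.

    ``snp_map`` has columns ``snp``, ``chrom`` (string label, empty/NaN if
    unknown) and ``pos`` (NaN or 0 if unknown), one row per column of
    ``dosages``.
    """

    dosages: np.ndarray
    animal_ids: tuple[str, ...]
    snp_map: pd.DataFrame
    imputed: bool = False  # imputed panels hold real-valued dosages in [0, 2]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = tuple(str(a) for a in self.animal_ids)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D animals x SNPs matrix")
        n, m = self.dosages.shape
        if n != len(self.animal_ids):
            raise ValidationError("dosage rows do not match animal ids")
        if len(set(self.animal_ids)) != n:
            raise ValidationError("duplicate animal ids in genotype panel")
        required = {"snp", "chrom", "pos"}
        if not required.issubset(self.snp_map.columns):
            raise ValidationError(f"snp_map must have columns {sorted(required)}")
        if len(self.snp_map) != m:
            raise ValidationError("snp_map rows do not match dosage columns")
        vals = self.dosages[~np.isnan(self.dosages)]
        if self.imputed:
            if vals.size and ((vals < 0.0) | (vals > 2.0)).any():
                raise ValidationError("imputed dosages must lie in [0, 2]")
        elif vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be coded {0, 1, 2, missing}")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def row(self, animal_id: str) -> np.ndarray:
        try:
            i = self.animal_ids.index(str(animal_id))
        except ValueError:
            raise KeyError(f"animal {animal_id!r} not genotyped") from None
        return self.dosages[i]

    def take_animals(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.dosages[keep],
            tuple(np.asarray(self.animal_ids, dtype=object)[keep]),
            self.snp_map.copy(),
            imputed=self.imputed,
        )

    def take_snps(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.dosages[:, keep],
            self.animal_ids,
            self.snp_map.loc[keep].reset_index(drop=True),
            imputed=self.imputed,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP reference allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class QCStep:
    scope: str  # "animals" or "snps"
    name: str
    n_removed: int
    n_remaining: int
    params: dict = field(default_factory=dict)


@dataclass
class QCReport:
    """Ordered removal ledger; remaining counts must be internally consistent."""

    steps: list[QCStep] = field(default_factory=list)

    def add(self, step: QCStep) -> None:
        prev = self.last_remaining(step.scope)
        if prev is not None and step.n_remaining != prev - step.n_removed:
            raise ValidationError(
                f"QC accounting broken at step {step.name!r}: "
                f"{prev} - {step.n_removed} != {step.n_remaining}"
            )
        self.steps.append(step)

    def last_remaining(self, scope: str) -> int | None:
        for step in reversed(self.steps):
            if step.scope == scope:
                return step.n_remaining
        return None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scope": s.scope,
                    "step": s.name,
                    "n_removed": s.n_removed,
                    "n_remaining": s.n_remaining,
                    "params": ";".join(f"{k}={v}" for k, v in s.params.items()),
                }
                for s in self.steps
            ]
        )

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    def log_lines(self) -> list[str]:
        return [
            f"[qc:{s.scope}] {s.name}: removed {s.n_removed}, {s.n_remaining} remain"
            for s in self.steps
        ]


def _start_report(panel: GenotypePanel, report: QCReport | None, scope: str) -> QCReport:
    report = report if report is not None else QCReport()
    if report.last_remaining(scope) is None:
        n0 = panel.n_animals if scope == "animals" else panel.n_snps
        report.add(QCStep(scope, "input", 0, n0))
    return report


def filter_animals_missingness(
    panel: GenotypePanel,
    max_missing_rate: float = 0.10,
    report: QCReport | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Remove animals whose missing-call fraction is strictly above threshold."""
    if panel.n_animals == 0 or panel.n_snps == 0:
        raise ValidationError("empty genotype panel")
    if not 0.0 < max_missing_rate < 1.0:
        raise ValidationError("max_missing_rate must be in (0, 1)")
    report = _start_report(panel, report, "animals")
    miss = np.isnan(panel.dosages).mean(axis=1)
    keep = miss <= max_missing_rate
    panel = panel.take_animals(keep)
    report.add(
        QCStep(
            "animals",
            "missingness",
            int((~keep).sum()),
            panel.n_animals,
            {"max_missing_rate": max_missing_rate},
        )
    )
    return panel, report


def remove_animals(
    panel: GenotypePanel,
    animal_ids,
    step_name: str,
    report: QCReport | None = None,
    **params,
) -> tuple[GenotypePanel, QCReport]:
    """Drop named animals (e.g. parentage conflicts) with ledger accounting."""
    report = _start_report(panel, report, "animals")
    drop = {str(a) for a in animal_ids}
    keep = np.array([a not in drop for a in panel.animal_ids])
    panel = panel.take_animals(keep)
    report.add(QCStep("animals", step_name, int((~keep).sum()), panel.n_animals, params))
    return panel, report


def filter_snps(
    panel: GenotypePanel,
    call_rate_min: float = 0.98,
    maf_min: float = 0.01,
    het_dev_max: float = 0.15,
    drop_unknown_position: bool = True,
    autosomes=DEFAULT_AUTOSOMES,
    report: QCReport | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """SNP filters in fixed order: unknown position, sex chromosomes,
    call rate, MAF, heterozygosity departure from 2p(1-p).

    Inequalities are strict: a SNP fails call rate when rate < threshold,
    fails MAF when maf < threshold, fails the heterozygosity check when
    |observed het - 2p(1-p)| > threshold. Each step sees only markers
    surviving the previous steps.
    """
    for nm, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                  ("het_dev_max", het_dev_max)):
        if not 0.0 < v < 1.0:
            raise ValidationError(f"{nm} must be in (0, 1)")
    autosomes = {str(c) for c in autosomes}
    if not autosomes:
        raise ValidationError("autosome label set is empty")
    report = _start_report(panel, report, "snps")

    chrom = panel.snp_map["chrom"].astype("string")
    pos = pd.to_numeric(panel.snp_map["pos"], errors="coerce")
    if drop_unknown_position:
        known = (~chrom.isna()) & (chrom != "") & (~pos.isna()) & (pos > 0)
        keep = known.to_numpy(dtype=bool)
        panel = panel.take_snps(keep)
        report.add(QCStep("snps", "unknown_position", int((~keep).sum()), panel.n_snps))
        chrom = panel.snp_map["chrom"].astype("string")

    keep = chrom.fillna("").isin(autosomes).to_numpy(dtype=bool)
    panel = panel.take_snps(keep)
    report.add(QCStep("snps", "sex_chromosomes", int((~keep).sum()), panel.n_snps,
                      {"autosomes": f"1-{len(autosomes)}"}))

    call_rate = 1.0 - np.isnan(panel.dosages).mean(axis=0)
    keep = call_rate >= call_rate_min
    panel = panel.take_snps(keep)
    report.add(QCStep("snps", "call_rate", int((~keep).sum()), panel.n_snps,
                      {"call_rate_min": call_rate_min}))

    p = panel.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    panel = panel.take_snps(keep)
    report.add(QCStep("snps", "maf", int((~keep).sum()), panel.n_snps,
                      {"maf_min": maf_min}))

    p = panel.allele_frequencies()
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_het = (
            (panel.dosages == 1.0).sum(axis=0)
            / (~np.isnan(panel.dosages)).sum(axis=0)
        )
    dev = np.abs(obs_het - 2.0 * p * (1.0 - p))
    keep = dev <= het_dev_max
    panel = panel.take_snps(keep)
    report.add(QCStep("snps", "het_departure", int((~keep).sum()), panel.n_snps,
                      {"het_dev_max": het_dev_max}))
    return panel, report


def mendelian_conflict_rate(panel: GenotypePanel, pairs) -> pd.DataFrame:
    """Opposing-homozygote rate for (sire, offspring) pairs.

    The rate is the fraction of jointly non-missing SNPs where one member
    is homozygous 0 and the other homozygous 2 — impossible under correct
    parentage absent genotyping error. Pairs above the 2% exclusion
    threshold, and pairs with no informative SNP (rate NaN), are flagged.
    """
    rows = []
    for sire_id, off_id in pairs:
        gs, go = panel.row(sire_id), panel.row(off_id)
        both = ~np.isnan(gs) & ~np.isnan(go)
        n_inf = int(both.sum())
        if n_inf == 0:
            rate = math.nan
            flagged = True
        else:
            opposing = ((gs == 0.0) & (go == 2.0)) | ((gs == 2.0) & (go == 0.0))
            rate = float((opposing & both).sum() / n_inf)
            flagged = rate > MENDELIAN_RATE_THRESHOLD
        rows.append(
            {"sire": str(sire_id), "offspring": str(off_id),
             "n_informative": n_inf, "conflict_rate": rate, "flagged": flagged}
        )
    return pd.DataFrame(rows, columns=["sire", "offspring", "n_informative",
                                       "conflict_rate", "flagged"])


def detect_pedigree_genomic_conflicts(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    dup_g_min: float = 0.9,
    rel_g_min: float = 0.15,
    rel_a_max: float = 0.05,
    rel_a_min: float = 0.15,
    rel_g_max: float = 0.05,
) -> pd.DataFrame:
    """Classify animal pairs whose genomic and pedigree relationships disagree.

    duplicate:        G_ij >= dup_g_min, with the threshold scaled down by
                      the pair's smaller diagonal when that diagonal is
                      below 1 — a duplicated sample satisfies
                      G_ij ~ G_ii ~ G_jj, and the self-relationship of a
                      low-heterozygosity animal legitimately sits below 1
                      when G is centered at observed frequencies
    missed_relative:  G >= rel_g_min while A <= rel_a_max (related by DNA,
                      unrelated on paper)
    false_relative:   A >= rel_a_min while G <= rel_g_max (e.g. recorded
                      half-sibs that are genomically unrelated)
    """
    if G.ids != A22.ids:
        raise AlignmentError("G and A22 must share the same id order")
    g = G.dense()
    a = A22.dense()
    n = G.n
    iu, ju = np.triu_indices(n, k=1)
    gv, av = g[iu, ju], a[iu, ju]
    diag = np.diag(g)
    pair_scale = np.minimum(1.0, np.minimum(diag[iu], diag[ju]))
    dup = gv >= dup_g_min * pair_scale
    missed = ~dup & (gv >= rel_g_min) & (av <= rel_a_max)
    false_rel = (av >= rel_a_min) & (gv <= rel_g_max)
    rows = []
    for mask, label in ((dup, "duplicate"), (missed, "missed_relative"),
                        (false_rel, "false_relative")):
        for k in np.flatnonzero(mask):
            rows.append(
                {"id1": G.ids[iu[k]], "id2": G.ids[ju[k]], "class": label,
                 "g": float(gv[k]), "a": float(av[k])}
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "class", "g", "a"])


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages with the per-SNP mean dosage 2*p_hat.

    The result is a real-valued panel (imputed entries are generally not
    integers); a SNP with every call missing is an error because it should
    have failed the call-rate filter upstream.
    """
    d = panel.dosages.copy()
    miss = np.isnan(d)
    if not miss.any():
        return panel
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = panel.snp_map["snp"].iloc[int(np.flatnonzero(all_missing)[0])]
        raise ValidationError(f"SNP {bad!r} has no observed calls; run filter_snps first")
    col_mean = np.nanmean(d, axis=0)
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return replace(panel, dosages=d, imputed=True)
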