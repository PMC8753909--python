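"""Weighted polygenic risk score (PRS) construction.

A PRS is a per-individual weighted sum of risk-allele dosages across a panel
of trait-associated variants,

    raw_i = sum_j beta_j * d_ij ,

with dosages ``d_ij`` in [0, 2] and per-allele weights ``beta_j`` oriented so
that every effect allele is the BMI-increasing allele.  The raw score is then

* allele-scaled — divided by twice the sum of the weights and multiplied by
  twice the variant count ``2N`` (the maximum possible number of risk
  alleles), so that the score reads as an equivalent count of risk alleles in
  [0, 2N]; and
* standardized to mean 0, SD 1 (sample SD), so effects read per SD of score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_PANEL_COLUMNS = ("variant_id", "effect_allele", "other_allele", "weight", "freq")
_VALID_ALLELES = frozenset("ACGT")
#: strand-ambiguous allele pairs (indistinguishable from their complement)
_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


class PanelError(ValueError):
    """Raised for malformed variant-weight tables."""


@dataclass(frozen=True)
class VariantPanel:
    """A panel of score variants: effect allele, weight and allele frequency.

    ``table`` has one row per variant with at least the columns
    ``variant_id, effect_allele, other_allele, weight, freq``.  Weights are in
    kg/m^2 per effect allele and must be strictly positive (harmonization to
    the risk-increasing allele happens at load time).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise PanelError(f"variant panel is missing required column(s): {missing}")
        if len(self.table) == 0:
            raise PanelError("variant panel is empty")
        ids = self.table["variant_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise PanelError(f"duplicate variant id(s) in panel: {dups}")
        for col in ("effect_allele", "other_allele"):
            bad = ~self.table[col].isin(list(_VALID_ALLELES))
            if bad.any():
                raise PanelError(
                    f"invalid allele(s) in column {col!r}: "
                    f"{sorted(self.table.loc[bad, col].unique())}"
                )
        w = self.table["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise PanelError("panel weights must be finite and strictly positive after harmonization")
        f = self.table["freq"].to_numpy(float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0) or np.any(f >= 1):
            raise PanelError("allele frequencies must lie strictly in (0, 1)")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    @property
    def freqs(self) -> np.ndarray:
        return self.table["freq"].to_numpy(float)


def load_variant_weights(path: str | Path) -> VariantPanel:
    """Load a variant weight TSV and harmonize weights to risk alleles.

    Rows with a negative weight are flipped: effect and other allele are
    swapped and the weight negated, so that every stored effect allele is the
    score-increasing allele.  Flips are logged.  Strand-ambiguous variants
    (A/T or C/G) are kept but trigger a warning, since their orientation
    cannot be checked against an external source.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in tab.columns]
    if missing:
        raise PanelError(f"weight table {path} is missing required column(s): {missing}")
    if len(tab) == 0:
        raise PanelError(f"weight table {path} contains no variants")

    neg = tab["weight"] < 0
    if neg.any():
        flipped = tab.loc[neg, "variant_id"].tolist()
        log.info("flipping %d variant(s) to the risk-increasing allele: %s", len(flipped), flipped)
        ea = tab.loc[neg, "effect_allele"].copy()
        tab.loc[neg, "effect_allele"] = tab.loc[neg, "other_allele"].values
        tab.loc[neg, "other_allele"] = ea.values
        tab.loc[neg, "weight"] = -tab.loc[neg, "weight"]
        tab.loc[neg, "freq"] = 1.0 - tab.loc[neg, "freq"]

    ambiguous = [
        vid
        for vid, a, b in zip(tab["variant_id"], tab["effect_allele"], tab["other_allele"])
        if frozenset((a, b)) in _AMBIGUOUS_PAIRS
    ]
    if ambiguous:
        warnings.warn(
            f"{len(ambiguous)} strand-ambiguous (A/T or C/G) variant(s) kept as-is: {ambiguous}",
            stacklevel=2,
        )
    return VariantPanel(tab.reset_index(drop=True))


def default_panel() -> VariantPanel:
    """The synthetic 97-variant panel shipped with the package.

    Frequencies and weights are drawn once from the distributions documented
    in the methods note; the panel is a stand-in for a published 97-SNP BMI
    score whose weight table is not redistributed here.
    """
    with resources.as_file(
        resources.files("prslife.data") / "variant_panel_synthetic.tsv"
    ) as p:
        return load_variant_weights(p)


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-d array")
    if x.size < 2:
        raise ValueError("standardize requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("standardize requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _dosage_matrix(dosages: pd.DataFrame, panel: VariantPanel, mean_impute: bool) -> np.ndarray:
    missing = [v for v in panel.variant_ids if v not in dosages.columns]
    if missing:
        raise KeyError(f"panel variant(s) missing from dosage table: {missing}")
    d = dosages[panel.variant_ids].to_numpy(float)
    if np.isnan(d).any():
        if not mean_impute:
            raise ValueError(
                "missing dosages present; pass mean_impute=True to impute column means"
            )
        col_means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = np.take(col_means, idx[1])
    if d.size and (np.nanmin(d) < 0 or np.nanmax(d) > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return d


def weighted_score(dosages: pd.DataFrame, panel: VariantPanel, mean_impute: bool = False) -> pd.Series:
    """Raw weighted score sum_j beta_j * d_ij per participant.

    ``dosages`` is participants x variants with columns named by variant id.
    Panel variants absent from the dosage table are a hard error — variants
    are never silently skipped.
    """
    d = _dosage_matrix(dosages, panel, mean_impute)
    return pd.Series(d @ panel.weights, index=dosages.index, name="raw")


def allele_scale_score(raw: pd.Series | np.ndarray, panel: VariantPanel) -> pd.Series:
    """Rescale a raw score to an equivalent risk-allele count in [0, 2N].

    scaled = raw / (2 * sum_j beta_j) * 2N, so a participant homozygous for
    every risk allele scores exactly 2N and an all-heterozygote scores N.
    """
    total = float(panel.weights.sum())
    if total <= 0:
        raise ValueError("sum of panel weights must be positive")
    scaled = np.asarray(raw, dtype=float) / (2.0 * total) * (2.0 * panel.n_variants)
    index = raw.index if isinstance(raw, pd.Series) else None
    return pd.Series(scaled, index=index, name="allele_scaled")


@dataclass(frozen=True)
class ScoreResult:
    """Per-participant PRS on its three scales (raw, allele count, z)."""

    frame: pd.DataFrame = field(repr=False)  # columns: raw, allele_scaled, z
    n_variants_used: int = 0

    @property
    def z(self) -> pd.Series:
        return self.frame["z"]

    @property
    def allele_scaled(self) -> pd.Series:
        return self.frame["allele_scaled"]

    def to_csv(self, path: str | Path) -> None:
        self.frame.rename_axis("participant_id").to_csv(path)


def compute_scores(dosages: pd.DataFrame, panel: VariantPanel, mean_impute: bool = False) -> ScoreResult:
    """Full scoring path: raw weighted sum -> allele scale -> z-standardize."""
    raw = weighted_score(dosages, panel, mean_impute=mean_impute)
    scaled = allele_scale_score(raw, panel)
    z = pd.Series(standardize(scaled.to_numpy()), index=dosages.index, name="z")
    frame = pd.DataFrame({"raw": raw, "allele_scaled": scaled, "z": z})
    return ScoreResult(frame=frame, n_variants_used=panel.n_variants)


def load_dosages_tsv(path: str | Path) -> pd.DataFrame:
    """Wide dosage TSV: first column participant_id, one column per variant."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    return df.set_index("participant_id")


def load_dosages_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with a DS FORMAT field into a participants x variants frame."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for variant in vcf:
        ds = variant.format("DS")
        if ds is None:
            raise ValueError(f"variant {variant.ID} has no DS field")
        ids.append(variant.ID)
        cols.append(np.asarray(ds, dtype=float).reshape(-1))
    vcf.close()
    return pd.DataFrame(np.column_stack(cols), index=pd.Index(samples, name="participant_id"), columns=ids)


def write_dosages_vcf(dosages: pd.DataFrame, panel: VariantPanel, path: str | Path) -> None:
    """Write dosages as a sites x samples VCF with a DS FORMAT field."""
    tab = panel.table
    chrom = tab["chrom"] if "chrom" in tab.columns else pd.Series(["1"] * len(tab))
    pos = tab["pos"] if "pos" in tab.columns else pd.Series(range(1000, 1000 + 10 * len(tab), 10))
    samples = list(dosages.index)
    d = _dosage_matrix(dosages, panel, mean_impute=False)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the effect allele">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, row in enumerate(tab.itertuples(index=False)):
            vals = "\t".join(format(v, "g") for v in d[:, j])
            fh.write(
                f"{chrom.iloc[j]}\t{pos.iloc[j]}\t{row.variant_id}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\t.\t.\tDS\t{vals}\n"
            )
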