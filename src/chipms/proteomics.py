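"""Label-free AP-MS differential enrichment.

Implements the standard workflow from a MaxQuant-style protein-group
intensity table to a classified volcano output:

1. filter protein groups (decoy/contaminant/only-by-site flags, minimum
   unique+razor peptide count, minimum valid values per condition);
2. log2-transform and median-center each sample column;
3. impute missing values with a low per-column percentile (2.5 by default),
   the usual treatment for missing-not-at-random dropout of low-abundance
   proteins;
4. moderated t-test per protein (empirical-Bayes variance shrinkage with
   moment matching on log residual variances);
5. Benjamini-Hochberg FDR adjustment;
6. gate significant interactors on fold change and FDR.

Two significance gates are provided and never silently mixed: the stringent
``methods`` gate (log2 fold change > 7 and BH-adjusted p <= 0.01) and the
permissive ``figure`` gate (log2 fold change > 3 and raw p < 1e-4); which
gate was applied is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityTable",
    "EnrichmentResult",
    "read_intensity_table",
    "write_intensity_table",
    "filter_proteins",
    "log2_median_center",
    "impute_low_percentile",
    "moderated_ttest",
    "bh_adjust",
    "classify_interactors",
    "recovery_score",
    "run_enrichment",
]

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ["protein_id", "is_reverse", "is_contaminant", "only_by_site", "unique_razor_peptides"]


@dataclass
class IntensityTable:
    """Proteins x samples intensity matrix with QC flags and condition labels.

    ``proteins``: DataFrame with FLAG_COLUMNS; ``intensities``: DataFrame
    indexed by protein_id, one column per sample, NaN marking missing values
    (zeros are converted to NaN at ingest); ``conditions``: Series mapping
    sample name to 'bait' or 'ctrl'. ``log2_transformed`` records whether
    the matrix is on the log2 scale.
    """

    proteins: pd.DataFrame
    intensities: pd.DataFrame
    conditions: pd.Series
    log2_transformed: bool = False
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.proteins.columns) != FLAG_COLUMNS:
            raise ValueError(f"protein table must have columns {FLAG_COLUMNS}")
        if not self.proteins["protein_id"].is_unique:
            raise ValueError("protein ids must be unique")
        if not (self.intensities.index == self.proteins["protein_id"].values).all():
            raise ValueError("intensity rows must align with protein table")
        conds = set(self.conditions)
        if not conds <= {"bait", "ctrl"}:
            raise ValueError(f"conditions must be 'bait'/'ctrl', got {conds}")
        for cond in ("bait", "ctrl"):
            if (self.conditions == cond).sum() < 2:
                raise ValueError(f"need >= 2 samples in condition {cond!r}")
        if list(self.intensities.columns) != list(self.conditions.index):
            raise ValueError("intensity columns must match condition labels")
        if not self.log2_transformed:
            vals = self.intensities.to_numpy()
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise ValueError("raw intensities must be > 0 (zeros are coded missing)")

    def samples(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    def evolve(self, step: str, **changes) -> "IntensityTable":
        out = replace(self, **changes)
        out.history = [*self.history, step]
        return out


def read_intensity_table(path, condition_map: dict[str, str] | None = None) -> IntensityTable:
    """Read a TSV with flag columns followed by one intensity column per sample.

    Conditions come from ``condition_map`` or from the ``bait_*`` / ``ctrl_*``
    column-name convention. Zero intensities are converted to missing (NaN)
    and the conversion is logged.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in FLAG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in FLAG_COLUMNS]
    if condition_map is None:
        condition_map = {}
        for c in sample_cols:
            if c.startswith("bait"):
                condition_map[c] = "bait"
            elif c.startswith("ctrl"):
                condition_map[c] = "ctrl"
            else:
                raise ValueError(f"cannot infer condition of sample column {c!r}")
    intens = df[sample_cols].astype(float)
    n_zero = int((intens.to_numpy() == 0).sum())
    if n_zero:
        logger.info("converted %d zero intensities to missing", n_zero)
        intens = intens.replace(0.0, np.nan)
    proteins = df[FLAG_COLUMNS].copy()
    for c in ("is_reverse", "is_contaminant", "only_by_site"):
        proteins[c] = proteins[c].astype(bool)
    return IntensityTable(
        proteins=proteins,
        intensities=intens.set_axis(proteins["protein_id"].values, axis=0),
        conditions=pd.Series({c: condition_map[c] for c in sample_cols}, name="condition"),
        history=[f"read({path})"],
    )


def write_intensity_table(table: IntensityTable, path, precision: int = 6) -> None:
    """Write the table as TSV; missing cells become 0 (MaxQuant convention)."""
    out = table.proteins.copy()
    intens = table.intensities.reset_index(drop=True)
    for c in intens.columns:
        out[c] = intens[c].round(precision).fillna(0.0)
    out.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")


def filter_proteins(
    table: IntensityTable,
    min_peptides: int = 2,
    min_valid: int = 3,
    valid_rule: str = "any",
) -> tuple[IntensityTable, dict[str, int]]:
    """Apply the protein-group QC filters.

    Removes rows flagged reverse/contaminant/only-by-site, rows with fewer
    than ``min_peptides`` unique+razor peptides, and rows failing the
    valid-values rule: with ``valid_rule='any'`` (default) a protein is kept
    iff it has >= ``min_valid`` non-missing values in at least one condition
    (a bait-specific interactor is legitimately absent from controls);
    ``'all'`` requires it in every condition. Returns the filtered table and
    per-rule removal counts.
    """
    if valid_rule not in ("any", "all"):
        raise ValueError("valid_rule must be 'any' or 'all'")
    p = table.proteins
    flagged = p["is_reverse"] | p["is_contaminant"] | p["only_by_site"]
    few_peptides = ~flagged & (p["unique_razor_peptides"] < min_peptides)
    valid_by_cond = []
    for cond in ("bait", "ctrl"):
        cols = table.samples(cond)
        valid_by_cond.append(table.intensities[cols].notna().sum(axis=1) >= min_valid)
    agg = valid_by_cond[0] | valid_by_cond[1] if valid_rule == "any" else valid_by_cond[0] & valid_by_cond[1]
    invalid = ~flagged.values & ~few_peptides.values & ~agg.values
    keep = ~(flagged.values | few_peptides.values | invalid)
    counts = {
        "flagged": int(flagged.sum()),
        "few_peptides": int(few_peptides.sum()),
        "too_few_valid_values": int(invalid.sum()),
        "kept": int(keep.sum()),
    }
    if counts["kept"] == 0:
        raise ValueError(
            "all proteins removed by filters; relax min_peptides/min_valid or check input"
        )
    out = table.evolve(
        f"filter(min_peptides={min_peptides}, min_valid={min_valid}, rule={valid_rule})",
        proteins=p[keep].reset_index(drop=True),
        intensities=table.intensities[keep],
    )
    return out, counts


def log2_median_center(table: IntensityTable) -> IntensityTable:
    """log2-transform and median-center each sample column.

    Each column's non-missing log2 values are shifted by a per-column
    constant so that every column median equals the grand median of the
    pre-shift column medians; missing cells are untouched. Differences
    between samples (hence fold changes) are invariant to the target choice.
    """
    if table.log2_transformed:
        raise ValueError("table is already log2-transformed")
    log2 = np.log2(table.intensities)
    medians = log2.median(axis=0, skipna=True)
    target = float(np.median(medians))
    centered = log2 + (target - medians)
    return table.evolve(
        "log2_median_center", intensities=centered, log2_transformed=True
    )


def impute_low_percentile(table: IntensityTable, q: float = 2.5) -> tuple[IntensityTable, pd.DataFrame]:
    """Replace missing cells with the q-th percentile of each column.

    Percentiles interpolate linearly between order statistics
    (h = (n-1)q/100 + 1). Returns the completed table and a boolean mask of
    imputed cells. Requires >= 2 observed values per column.
    """
    if not (0 <= q <= 100):
        raise ValueError("percentile must be in [0, 100]")
    intens = table.intensities.copy()
    mask = intens.isna()
    for col in intens.columns:
        observed = intens[col].dropna().to_numpy()
        if observed.size == 0:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if observed.size < 2:
            raise ValueError(f"column {col!r} has < 2 observed values")
        fill = float(np.percentile(observed, q))
        intens[col] = intens[col].fillna(fill)
    out = table.evolve(f"impute_low_percentile(q={q})", intensities=intens)
    return out, mask


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to residual variances.

    Works on z = log(s^2): with s^2 ~ s0^2 * chi2_d / d under the prior,
    E[z] and Var[z] have closed forms in digamma/trigamma; inverting the
    trigamma relation gives the prior degrees of freedom d0, and the mean
    relation gives the prior variance s0^2. Returns (inf, geometric-mean
    variance) when the observed spread of log variances is no larger than
    expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 positive residual variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def moderated_ttest(
    table: IntensityTable,
    d0_override: float | None = None,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-protein moderated t-test of bait vs control log2 intensities.

    For protein i with pooled residual variance s_i^2 on d = n_bait +
    n_ctrl - 2 degrees of freedom, the empirical-Bayes posterior variance is
    ``(d0*s0^2 + d*s_i^2) / (d0 + d)`` with (d0, s0^2) moment-matched across
    all proteins; the moderated t is the mean difference over the shrunken
    standard error, with two-sided p from a t distribution on d0 + d df.

    ``d0_override`` forces the prior df (``np.inf`` gives the analytic limit
    where every protein uses the common variance s0^2);
    ``method='welch'`` computes an ordinary Welch t instead. If the prior
    cannot be estimated the function falls back to an ordinary pooled
    two-sample t with a warning.

    Requires a complete (post-imputation) log2 table.
    """
    if not table.log2_transformed:
        raise ValueError("moderated_ttest expects a log2-transformed table")
    if table.intensities.isna().any().any():
        raise ValueError("table has missing values; impute before testing")
    bait = table.intensities[table.samples("bait")].to_numpy()
    ctrl = table.intensities[table.samples("ctrl")].to_numpy()
    n1, n2 = bait.shape[1], ctrl.shape[1]
    mean_b, mean_c = bait.mean(axis=1), ctrl.mean(axis=1)
    fc = mean_b - mean_c

    if method == "welch":
        t, p = stats.ttest_ind(bait, ctrl, axis=1, equal_var=False)
        df_used = np.full(fc.shape, np.nan)
        d0, s0_2 = np.nan, np.nan
    elif method == "moderated":
        d = n1 + n2 - 2
        s2 = (bait.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / d
        if d0_override is not None:
            d0 = float(d0_override)
            _, s0_2 = estimate_variance_prior(s2, d)
        else:
            try:
                d0, s0_2 = estimate_variance_prior(s2, d)
            except ValueError as exc:
                logger.warning("variance prior estimation failed (%s); using ordinary t", exc)
                d0, s0_2 = 0.0, 0.0
        if d0 == 0.0 and s0_2 == 0.0:  # fallback: ordinary pooled t
            se = np.sqrt(s2 * (1 / n1 + 1 / n2))
            t = np.divide(fc, se, out=np.zeros_like(fc), where=se > 0)
            df_total = float(d)
        else:
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0_2)
                df_total = 1e6  # effectively normal tail
            else:
                s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
                df_total = d0 + d
            se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
            t = np.divide(fc, se, out=np.zeros_like(fc), where=se > 0)
        p = 2 * stats.t.sf(np.abs(t), df_total)
        df_used = np.full(fc.shape, df_total)
    else:
        raise ValueError("method must be 'moderated' or 'welch'")

    return pd.DataFrame(
        {
            "protein_id": table.proteins["protein_id"].values,
            "log2_fc": fc,
            "t_mod": t,
            "p": p,
            "df": df_used,
            "prior_d0": d0,
            "prior_s0_2": s0_2,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    rows: pd.DataFrame  # protein_id, log2_fc, t_mod, p, adj_p, significant
    gate: str
    params: dict


def classify_interactors(
    rows: pd.DataFrame,
    fc_cutoff_log2: float = 7.0,
    fdr: float = 0.01,
    gate: str = "methods",
    figure_fc_log2: float = 3.0,
    figure_neg_log10_p: float = 4.0,
) -> EnrichmentResult:
    """Gate enrichment rows into significant interactors.

    ``gate='methods'``: log2 fold change > ``fc_cutoff_log2`` AND BH-adjusted
    p <= ``fdr``. ``gate='figure'``: log2 fold change > ``figure_fc_log2``
    AND -log10(raw p) > ``figure_neg_log10_p``. The gate applied is recorded
    in the result metadata.
    """
    out = rows.copy()
    if "adj_p" not in out.columns:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    if gate == "methods":
        sig = (out["log2_fc"] > fc_cutoff_log2) & (out["adj_p"] <= fdr)
        params = {"fc_cutoff_log2": fc_cutoff_log2, "fdr": fdr}
    elif gate == "figure":
        with np.errstate(divide="ignore"):
            neglog = -np.log10(out["p"].to_numpy())
        sig = (out["log2_fc"] > figure_fc_log2) & (neglog > figure_neg_log10_p)
        params = {"fc_cutoff_log2": figure_fc_log2, "neg_log10_p": figure_neg_log10_p}
    else:
        raise ValueError("gate must be 'methods' or 'figure'")
    out["significant"] = sig.to_numpy() if hasattr(sig, "to_numpy") else sig
    return EnrichmentResult(rows=out, gate=gate, params=params)


def recovery_score(result: EnrichmentResult, truth) -> tuple[float, float]:
    """Precision and recall of significance calls against planted interactors.

    Precision is NaN (flagged by the caller via ``np.isnan``) when nothing
    was called significant.
    """
    planted = set(truth.planted_interactors["protein_id"])
    if not planted <= set(result.rows["protein_id"]) and not planted:
        raise ValueError("truth interactors missing from result rows")
    called = set(result.rows.loc[result.rows["significant"], "protein_id"])
    tp = len(called & planted)
    fp = len(called - planted)
    fn = len(planted - called)
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    return precision, recall


def run_enrichment(
    table: IntensityTable,
    min_peptides: int = 2,
    min_valid: int = 3,
    valid_rule: str = "any",
    impute_q: float = 2.5,
    gate: str = "methods",
    fc_cutoff_log2: float = 7.0,
    fdr: float = 0.01,
) -> EnrichmentResult:
    """Full pipeline: filter -> log2 + median-center -> impute -> test -> BH -> gate.

    The stage order is fixed; each stage is recorded in the table history.
    """
    filtered, counts = filter_proteins(table, min_peptides, min_valid, valid_rule)
    centered = log2_median_center(filtered)
    imputed, mask = impute_low_percentile(centered, impute_q)
    rows = moderated_ttest(imputed)
    rows["adj_p"] = bh_adjust(rows["p"].to_numpy())
    n_imp = mask.sum(axis=1)
    rows["n_imputed"] = n_imp.to_numpy()
    result = classify_interactors(rows, fc_cutoff_log2=fc_cutoff_log2, fdr=fdr, gate=gate)
    result.params.update({"filter_counts": counts, "impute_q": impute_q})
    return result
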