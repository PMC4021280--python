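"""Association statistics between structural sensitivity and conservation.

Per gene, 4-fold degenerate sites are cross-classified as structurally
sensitive/non-sensitive and conserved/non-conserved, giving one 2x2 table
per gene.  Tables are combined over genes with the Mantel-Haenszel
procedure:

    OR_MH = sum_i (a_i d_i / s_i) / sum_i (b_i c_i / s_i)

with a continuity-corrected chi-square test (two-sided) and a
Robins-Breslow-Greenland confidence interval.  OR_MH > 1 means sensitive
sites tend to be conserved.  A complementary continuous test uses the mean
over genes of the per-gene Pearson correlation between sensitivity and
E_w, calibrated by constrained permutation: E_w values are reshuffled only
among sites sharing the same reference nucleotide within each gene, which
preserves each gene's amino acid sequence, codon bias and composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "MHResult",
    "CorrTestResult",
    "gene_table",
    "mantel_haenszel",
    "run_species_analysis",
    "stratified_analysis",
    "sliding_windows",
    "windowed_analysis",
    "constrained_permutation_test",
    "regional_correlation_test",
]


@dataclass
class ContingencyTable:
    """Per-gene 2x2 counts: (sensitive, non-sensitive) x (conserved, not)."""

    a: int  # sensitive & conserved
    b: int  # sensitive & non-conserved
    c: int  # non-sensitive & conserved
    d: int  # non-sensitive & non-conserved
    gene_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def s(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class MHResult:
    or_mh: float
    chi2: float
    p_two_sided: float
    ci95: tuple
    n_strata_used: int
    n_strata_skipped: int = 0


@dataclass
class CorrTestResult:
    mean_r: float
    null_means: np.ndarray
    p_left: float
    n_genes_used: int
    n_genes_excluded: int
    per_gene_r: dict = field(default_factory=dict)


def gene_table(site_records, e_cut: float = 0.5, s_cut: float = 0.1,
               gene_id: str = "") -> ContingencyTable:
    """Cross-classify one gene's sites by (E_w < e_cut) x (sensitivity > s_cut).

    Both thresholds are strict: E_w exactly at the cutoff counts as
    non-conserved and sensitivity exactly at the cutoff as non-sensitive.
    Sites with undefined E_w or sensitivity are skipped.
    """
    a = b = c = d = 0
    for s in site_records:
        if s.E_w is None or s.sensitivity is None:
            continue
        if math.isnan(s.E_w) or math.isnan(s.sensitivity):
            continue
        conserved = s.E_w < e_cut
        sensitive = s.sensitivity > s_cut
        if sensitive and conserved:
            a += 1
        elif sensitive:
            b += 1
        elif conserved:
            c += 1
        else:
            d += 1
        if not gene_id:
            gene_id = s.gene_id
    return ContingencyTable(a=a, b=b, c=c, d=d, gene_id=gene_id)


def mantel_haenszel(tables) -> MHResult:
    """Mantel-Haenszel pooled odds ratio with continuity-corrected test.

    Strata with fewer than 2 observations are skipped (and counted).  When
    the cross-product denominator is zero the OR is reported as +inf (or nan
    when both sums vanish); the chi-square p-value is still returned.
    """
    used = [t for t in tables if t.s >= 2]
    skipped = len(list(tables)) - len(used)
    if not used:
        raise ValueError("Mantel-Haenszel needs >= 1 stratum with s_i >= 2")
    num = den = 0.0
    sum_a = expect = var = 0.0
    # Robins-Breslow-Greenland components
    rbg_pr = rbg_ps_qr = rbg_qs = 0.0
    for t in used:
        s = t.s
        r_i = t.a * t.d / s
        s_i = t.b * t.c / s
        num += r_i
        den += s_i
        m1 = t.a + t.b
        m2 = t.c + t.d
        n1 = t.a + t.c
        n2 = t.b + t.d
        sum_a += t.a
        expect += m1 * n1 / s
        var += m1 * m2 * n1 * n2 / (s * s * (s - 1))
        p_i = (t.a + t.d) / s
        q_i = (t.b + t.c) / s
        rbg_pr += p_i * r_i
        rbg_ps_qr += p_i * s_i + q_i * r_i
        rbg_qs += q_i * s_i
    if var > 0:
        chi2 = (abs(sum_a - expect) - 0.5) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    if den > 0:
        or_mh = num / den
    else:
        or_mh = math.inf if num > 0 else math.nan
    if den > 0 and num > 0:
        var_log = (
            rbg_pr / (2 * num * num)
            + rbg_ps_qr / (2 * num * den)
            + rbg_qs / (2 * den * den)
        )
        half = 1.959963984540054 * math.sqrt(var_log)
        ci = (or_mh * math.exp(-half), or_mh * math.exp(half))
    else:
        ci = (math.nan, math.nan)
    return MHResult(
        or_mh=or_mh,
        chi2=chi2,
        p_two_sided=p,
        ci95=ci,
        n_strata_used=len(used),
        n_strata_skipped=skipped,
    )


def run_species_analysis(sites_by_gene: dict, e_cut: float = 0.5,
                         s_cut: float = 0.1):
    """Overall Mantel-Haenszel combination across all genes.

    Returns ``(MHResult, tables_by_gene, sensitive_fraction_by_gene)``.
    """
    tables = {}
    sensitive_fraction = {}
    for gid, sites in sites_by_gene.items():
        t = gene_table(sites, e_cut=e_cut, s_cut=s_cut, gene_id=gid)
        tables[gid] = t
        if t.s:
            sensitive_fraction[gid] = (t.a + t.b) / t.s
    result = mantel_haenszel(list(tables.values()))
    return result, tables, sensitive_fraction


def stratified_analysis(sites_by_gene: dict, covariate: dict,
                        higher_is_top: bool = True, e_cut: float = 0.5,
                        s_cut: float = 0.1) -> dict:
    """Mantel-Haenszel separately for the top and bottom covariate halves.

    ``covariate`` maps gene_id -> value (e.g. expression, ENC').  With
    ``higher_is_top=False`` the "top" group is the *lowest* values — used
    for ENC', where low values mean strongest codon bias.  Genes lacking a
    covariate value are excluded from this analysis only.
    """
    from .codonbias import median_split

    defined = {g: covariate[g] for g in sites_by_gene if g in covariate
               and covariate[g] is not None and not np.isnan(covariate[g])}
    excluded = sorted(set(sites_by_gene) - set(defined))
    high, low = median_split(defined)
    top_ids, bottom_ids = (high, low) if higher_is_top else (low, high)
    out = {}
    for label, ids in (("top", top_ids), ("bottom", bottom_ids)):
        tables = [
            gene_table(sites_by_gene[g], e_cut=e_cut, s_cut=s_cut, gene_id=g)
            for g in ids
        ]
        out[label] = mantel_haenszel(tables)
    out["top_ids"] = top_ids
    out["bottom_ids"] = bottom_ids
    out["excluded"] = excluded
    return out


def sliding_windows(win: int = 36, step: int = 12,
                    last_start: int = 109) -> list:
    """1-based inclusive window intervals [1, win], [1+step, win+step], ...

    Windows are emitted while the start does not exceed ``last_start``; the
    default scheme (36 nt window, 12 nt step, starts through nucleotide 109)
    yields 10 windows.
    """
    if min(win, step, last_start) <= 0:
        raise ValueError("win, step and last_start must all be positive")
    windows = []
    start = 1
    while start <= last_start:
        windows.append((start, start + win - 1))
        start += step
    return windows


def windowed_analysis(sites_by_gene: dict, windows=None, e_cut: float = 0.5,
                      s_cut: float = 0.1) -> list:
    """Mantel-Haenszel per sliding window along the CDS.

    A site belongs to every window whose interval contains its cds_pos
    (overlapping windows share sites).  Windows in which no gene contributes
    a usable stratum, or with no sensitive sites at all, report or_mh nan.
    Returns a list of dicts with window bounds, MHResult fields and the
    pooled sensitive-site fraction.
    """
    if windows is None:
        windows = sliding_windows()
    results = []
    for (lo, hi) in windows:
        tables = []
        n_sites = n_sensitive = 0
        for gid, sites in sites_by_gene.items():
            in_win = [s for s in sites if lo <= s.cds_pos <= hi]
            if not in_win:
                continue
            t = gene_table(in_win, e_cut=e_cut, s_cut=s_cut, gene_id=gid)
            tables.append(t)
            n_sites += t.s
            n_sensitive += t.a + t.b
        entry = {
            "window_start": lo,
            "window_end": hi,
            "n_sites": n_sites,
            "sensitive_fraction": (n_sensitive / n_sites) if n_sites else math.nan,
        }
        usable = [t for t in tables if t.s >= 2]
        if usable and n_sensitive > 0:
            mh = mantel_haenszel(usable)
            entry.update(
                or_mh=mh.or_mh, chi2=mh.chi2, p_two_sided=mh.p_two_sided,
                ci95=mh.ci95, n_strata_used=mh.n_strata_used,
            )
        else:
            entry.update(or_mh=math.nan, chi2=math.nan, p_two_sided=math.nan,
                         ci95=(math.nan, math.nan), n_strata_used=0)
        results.append(entry)
    return results


def _gene_arrays(sites):
    sens, ew, nts = [], [], []
    for s in sites:
        if s.E_w is None or s.sensitivity is None:
            continue
        if math.isnan(s.E_w) or math.isnan(s.sensitivity):
            continue
        sens.append(s.sensitivity)
        ew.append(s.E_w)
        nts.append(s.ref_nt)
    return np.asarray(sens), np.asarray(ew), np.asarray(nts)


def constrained_permutation_test(sites_by_gene: dict, n_perm: int = 1000,
                                 seed: int = 0) -> CorrTestResult:
    """Permutation test on the mean per-gene correlation(sensitivity, E_w).

    Within each gene, E_w values are reshuffled only among sites sharing the
    same reference nucleotide (classes with < 2 sites are fixed points); the
    statistic is the mean over genes of the Pearson correlation, and the
    left-tailed p-value uses the add-one estimator
    ``p = (1 + #{null <= observed}) / (1 + n_perm)`` so it can never be 0.

    Genes need >= 3 usable sites and variance in both variables; excluded
    genes are counted.  Per-gene permutation streams are split from the seed
    so results are reproducible gene by gene.
    """
    eligible = {}
    excluded = 0
    for gid, sites in sites_by_gene.items():
        sens, ew, nts = _gene_arrays(sites)
        if len(sens) < 3 or np.std(sens) == 0 or np.std(ew) == 0:
            excluded += 1
            continue
        eligible[gid] = (sens, ew, nts)
    if not eligible:
        raise ValueError("no gene has enough variable sites for the test")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(eligible))
    per_gene_r = {}
    null_sum = np.zeros(n_perm)
    obs_sum = 0.0
    for (gid, (sens, ew, nts)), child in zip(sorted(eligible.items()), children):
        n = len(sens)
        sc = sens - sens.mean()
        denom = n * sens.std() * ew.std()
        r_obs = float(sc @ (ew - ew.mean()) / denom)
        per_gene_r[gid] = r_obs
        obs_sum += r_obs
        rng = np.random.default_rng(child)
        perm = np.tile(ew, (n_perm, 1))
        for nt in np.unique(nts):
            idx = np.flatnonzero(nts == nt)
            if len(idx) < 2:
                continue
            perm[:, idx] = rng.permuted(perm[:, idx], axis=1)
        # permutation preserves each gene's E_w multiset, so mean/std are fixed
        null_sum += (perm - ew.mean()) @ sc / denom
    k = len(eligible)
    mean_r = obs_sum / k
    null_means = null_sum / k
    p_left = (1 + int(np.sum(null_means <= mean_r))) / (1 + n_perm)
    return CorrTestResult(
        mean_r=mean_r,
        null_means=null_means,
        p_left=p_left,
        n_genes_used=k,
        n_genes_excluded=excluded,
        per_gene_r=per_gene_r,
    )


def regional_correlation_test(sites_by_gene: dict, region: tuple,
                              n_perm: int = 1000, seed: int = 0) -> CorrTestResult:
    """Constrained permutation test restricted to a CDS region.

    ``region`` is a 1-based inclusive nucleotide interval, e.g. (1, 60) for
    translation initiation or (91, 150) for early elongation.
    """
    lo, hi = region
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid region {region}")
    restricted = {}
    for gid, sites in sites_by_gene.items():
        in_region = [s for s in sites if lo <= s.cds_pos <= hi]
        if in_region:
            restricted[gid] = in_region
    if not restricted:
        raise ValueError(f"no sites fall in region {region}")
    return constrained_permutation_test(restricted, n_perm=n_perm, seed=seed)
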