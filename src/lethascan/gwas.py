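"""Single-marker and haplotype association on deregressed EBVs.

Each marker is tested one at a time with the fixed-effect regression
y* = mu + b x + e, where y* are dEBVs and x is the allele-B dosage (0/1/2;
for a candidate haplotype the carrier dosage 0/1, homozygotes being absent
by construction). The effect is standardised to t = g_hat / SE(g_hat) and the
two-sided p-value taken from the t distribution with n-2 degrees of freedom
(a normal tail is available by flag). Markers are called significant at
-log10(p) > 6.

Significant markers are annotated with every gene whose span lies within
100 kb down- and upstream (inclusive at exactly 100,000 bp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

LOG10_E = np.log10(np.e)


@dataclass
class AssocResult:
    """One marker's (or haplotype's) association row."""

    marker: str
    chrom: str
    pos: int
    effect: float
    se: float
    t_value: float
    p_value: float
    minus_log10_p: float
    n: int
    significant: bool
    testable: bool


def _assoc_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [r.marker for r in results],
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "effect": [r.effect for r in results],
            "se": [r.se for r in results],
            "t_value": [r.t_value for r in results],
            "p_value": [r.p_value for r in results],
            "minus_log10_p": [r.minus_log10_p for r in results],
            "n": [r.n for r in results],
            "significant": [r.significant for r in results],
            "testable": [r.testable for r in results],
        }
    )


class MarkerAssociation(BaseEstimator):
    """Mass single-marker OLS on dEBVs.

    Parameters
    ----------
    threshold : -log10(p) significance cutoff (6.0 as in genome screens that
        print a fixed Bonferroni-style line).
    tail : 't' for the t distribution with n-2 df; 'normal' for the
        standard-normal tail.

    Attributes
    ----------
    results_ : list of AssocResult; frame_ : same as a DataFrame.
    """

    def __init__(self, threshold: float = 6.0, tail: str = "t"):
        self.threshold = threshold
        self.tail = tail

    def fit(self, dosages: pd.DataFrame, y: np.ndarray, marker_map: pd.DataFrame | None = None):
        """Test each dosage column against the response.

        dosages : DataFrame (animals x markers), entries in {0,1,2}.
        y : dEBV vector aligned with the dosage rows.
        marker_map : optional chrom/pos lookup indexed like the columns.
        """
        if self.tail not in ("t", "normal"):
            raise ValueError("tail must be 't' or 'normal'")
        y = np.asarray(y, dtype=float)
        if dosages.shape[0] != len(y):
            raise ValueError("dosages and response length differ")
        if len(y) < 3:
            raise ValueError("need at least 3 animals")
        results = []
        mm = None
        if marker_map is not None:
            mm = marker_map.set_index("id")
        for name in dosages.columns:
            x = dosages[name].to_numpy(dtype=float)
            chrom, pos = "", 0
            if mm is not None and name in mm.index:
                chrom, pos = str(mm.loc[name, "chrom"]), int(mm.loc[name, "pos"])
            results.append(_single_test(str(name), chrom, pos, x, y, self.threshold, self.tail))
        self.results_ = results
        self.frame_ = _assoc_frame(results)
        return self


def _single_test(name, chrom, pos, x, y, threshold, tail) -> AssocResult:
    n = len(x)
    sxx = float(np.var(x) * n)
    if sxx == 0.0 or np.var(y) == 0.0:
        return AssocResult(name, chrom, pos, 0.0, np.nan, np.nan, 1.0, 0.0, n, False, False)
    xc = x - x.mean()
    b = float(xc @ y) / sxx
    resid = y - y.mean() - b * xc
    df = n - 2
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 / sxx)
    t = b / se
    if tail == "t":
        logsf = stats.t.logsf(abs(t), df)
    else:
        logsf = stats.norm.logsf(abs(t))
    # p = 2*sf(|t|); kept in log space so -log10(p) survives tiny tails
    mlog10p = -(np.log(2.0) + logsf) * LOG10_E
    p = float(min(1.0, 2.0 * np.exp(logsf)))
    return AssocResult(
        name, chrom, pos, b, float(se), float(t), p, float(mlog10p), n,
        bool(mlog10p > threshold), True,
    )


def snp_association(
    debv: pd.DataFrame,
    dosages: pd.DataFrame,
    marker_map: pd.DataFrame | None = None,
    threshold: float = 6.0,
    tail: str = "t",
) -> pd.DataFrame:
    """Single-SNP regression of dEBVs on allele-B dosage, marker by marker.

    ``debv`` has columns animal/debv; dosage rows are indexed by animal id
    and are intersected with the dEBV animals before testing.
    """
    merged = debv.set_index("animal")["debv"]
    common = [a for a in dosages.index.astype(str) if a in merged.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 animals shared between dEBVs and genotypes")
    X = dosages.loc[common]
    y = merged.loc[common].to_numpy()
    est = MarkerAssociation(threshold=threshold, tail=tail).fit(X, y, marker_map)
    return est.frame_


def haplotype_association(
    debv: pd.DataFrame,
    carrier_ids,
    name: str = "haplotype",
    chrom: str = "",
    pos: int = 0,
    threshold: float = 6.0,
    tail: str = "t",
) -> AssocResult:
    """Association of carrier dosage (0/1) with dEBVs; positive effect =
    carriers have higher dEBV. Not testable when every or no analysed animal
    carries the haplotype."""
    carrier_set = {str(c) for c in carrier_ids}
    y = debv["debv"].to_numpy(dtype=float)
    x = debv["animal"].astype(str).isin(carrier_set).to_numpy(dtype=float)
    return _single_test(name, chrom, pos, x, y, threshold, tail)


def dosage_matrix(panel, markers: list | None = None) -> pd.DataFrame:
    """Allele-B (ALT) dosage per animal per marker from a phased panel."""
    d = panel.haplotypes.sum(axis=1)  # (n_animals, n_markers)
    cols = list(panel.marker_map["id"])
    df = pd.DataFrame(d, index=pd.Index([str(a) for a in panel.animals], name="animal"), columns=cols)
    if markers is not None:
        df = df[list(markers)]
    return df


@dataclass
class GeneWindowHit:
    marker: str
    chrom: str
    pos: int
    gene: str
    gene_start: int
    gene_end: int
    distance: int  # bp from marker to nearest gene edge, 0 if inside


def annotate_windows(
    results: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 100_000,
    only_significant: bool = True,
) -> pd.DataFrame:
    """Genes within ``window`` bp of each (significant) marker.

    A gene is reported when the marker window [pos-window, pos+window]
    (clamped at 1) overlaps the gene span, i.e. the marker-to-gene distance
    is at most ``window`` inclusive. ``genes`` needs columns
    chrom/start/end/gene with 1-based inclusive spans.
    """
    hits = results[results["significant"]] if only_significant else results
    res_chroms = set(hits["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    if len(hits) and len(genes) and not (res_chroms & gene_chroms):
        raise ValueError(
            "no chromosome name shared between association results and gene "
            f"table (results: {sorted(res_chroms)[:5]}, genes: {sorted(gene_chroms)[:5]})"
        )
    out = []
    for chrom, sub in hits.groupby(hits["chrom"].astype(str)):
        g = genes[genes["chrom"].astype(str) == chrom]
        if g.empty:
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        order = np.argsort(gs, kind="stable")
        gs_s, ge_s = gs[order], ge[order]
        names = g["gene"].to_numpy()[order]
        for _, row in sub.iterrows():
            pos = int(row["pos"])
            lo = max(1, pos - window)
            hi = pos + window
            # candidate genes: start <= hi; filter on end >= lo
            k = np.searchsorted(gs_s, hi, side="right")
            sel = np.flatnonzero(ge_s[:k] >= lo)
            for j in sel:
                if gs_s[j] <= pos <= ge_s[j]:
                    dist = 0
                elif pos < gs_s[j]:
                    dist = int(gs_s[j] - pos)
                else:
                    dist = int(pos - ge_s[j])
                out.append(
                    GeneWindowHit(
                        str(row["marker"]), chrom, pos, str(names[j]),
                        int(gs_s[j]), int(ge_s[j]), dist,
                    )
                )
    return pd.DataFrame(
        {
            "marker": [h.marker for h in out],
            "chrom": [h.chrom for h in out],
            "pos": [h.pos for h in out],
            "gene": [h.gene for h in out],
            "gene_start": [h.gene_start for h in out],
            "gene_end": [h.gene_end for h in out],
            "distance": [h.distance for h in out],
        }
    )


def cross_trait_overlap(per_trait: dict) -> dict:
    """Shared and trait-specific significant markers across traits.

    ``per_trait`` maps trait name -> association DataFrame. Returns a dict
    with every non-empty trait combination ("HR", "HR&STAY", ...) and its
    marker set, plus per-trait specific sets.
    """
    if len(per_trait) < 2:
        raise ValueError("need at least two traits")
    sig = {
        t: set(df.loc[df["significant"], "marker"].astype(str))
        for t, df in per_trait.items()
    }
    traits = sorted(sig)
    from itertools import combinations

    out = {"per_trait": {t: sorted(sig[t]) for t in traits}, "shared": {}, "specific": {}}
    for r in range(2, len(traits) + 1):
        for combo in combinations(traits, r):
            inter = set.intersection(*(sig[t] for t in combo))
            out["shared"]["&".join(combo)] = sorted(inter)
    for t in traits:
        others = set.union(*(sig[u] for u in traits if u != t)) if len(traits) > 1 else set()
        out["specific"][t] = sorted(sig[t] - others)
    return out
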