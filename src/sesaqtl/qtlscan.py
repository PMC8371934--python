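"""Interval mapping (IM) and composite interval mapping (CIM) on an F2
linkage map, with permutation-based significance thresholds.

The scan is Haley–Knott-style regression on conditional QTL genotype
probabilities: at each grid position the probabilities of the three F2
genotypes given the flanking bin codes are computed from Kosambi-inverted
recombination fractions under no-interference transition products, and the
phenotype is regressed on an additive predictor x = P(AA) - P(BB) and a
dominance predictor z = P(AH). The LOD at a position is

    LOD = (n / 2) * log10(RSS0 / RSS1)

comparing the model with and without the two QTL predictors. CIM adds
selected background marker cofactors to both models, excluding any cofactor
within a window of the test position. Genome-wide significance is the
(1 - alpha) quantile of the max-LOD distribution over phenotype
permutations (phenotypes are permuted against whole genotype rows, so the
marker correlation structure is preserved).

This regression approach is a deterministic, fast approximation to the
mixture-likelihood EM used by classic QTL software; at the effect sizes of
seed-coat-color QTLs the two are practically indistinguishable.

The module exposes both the individual operations (``scan_im``,
``scan_cim``, ``permutation_threshold``, ``select_cofactors``,
``call_qtls``) and a model-object facade: ``QTLScanModel(...).fit()``
returns a ``QTLScanResults`` carrying the LOD profile, the threshold, the
QTL calls with PVE, a ``summary()`` table and a ``plot()`` method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import A, B, H, MISSING
from .genmap import GeneticMap, kosambi_inverse

__all__ = [
    "ScanResult", "QTLCall", "genotype_probs_f2", "scan_im", "scan_cim",
    "permutation_threshold", "select_cofactors", "call_qtls",
    "QTLScanModel", "QTLScanResults",
]


# ----------------------------------------------------------- genotype probs

def _gamete_joint(r1: float, r2: float) -> np.ndarray:
    """P(haplotype at left flank, QTL, right flank) for one gamete;
    shape (2, 2, 2)."""
    out = np.empty((2, 2, 2))
    for hl in (0, 1):
        for hq in (0, 1):
            for hr in (0, 1):
                p = 0.5
                p *= r1 if hq != hl else 1.0 - r1
                p *= r2 if hr != hq else 1.0 - r2
                out[hl, hq, hr] = p
    return out


def _diploid_joint(r1: float, r2: float) -> np.ndarray:
    """P(genotype at left, QTL, right) as allele-B counts; shape (3,3,3)."""
    g = _gamete_joint(r1, r2)
    out = np.zeros((3, 3, 3))
    for i1 in np.ndindex(2, 2, 2):
        for i2 in np.ndindex(2, 2, 2):
            out[i1[0] + i2[0], i1[1] + i2[1], i1[2] + i2[2]] += g[i1] * g[i2]
    return out


def _conditional_table(r1: float, r2: float | None) -> np.ndarray:
    """Lookup P(QTL genotype | left code, right code), shape (4, 4, 3).

    Index 3 on either axis marginalizes that flank (missing code, or no
    flank at all when ``r2`` is None). Code order A, H, B matches the
    allele-count order because parent-2 alleles are counted.
    """
    joint = _diploid_joint(r1, 0.25 if r2 is None else r2)
    if r2 is None:
        joint = joint.sum(axis=2, keepdims=True).repeat(3, axis=2) / 3.0
    table = np.empty((4, 4, 3))
    for il in range(4):
        jl = joint if il == 3 else joint[il:il + 1]
        for ir in range(4):
            sub = jl if ir == 3 else jl[:, :, ir:ir + 1]
            mass = sub.sum(axis=(0, 2)) + 1e-300
            table[il, ir] = mass / mass.sum()
    return table


def genotype_probs_f2(codes_left: np.ndarray, codes_right: np.ndarray | None,
                      d_left_cM: float, d_right_cM: float | None
                      ) -> np.ndarray:
    """Per-individual (pAA, pAH, pBB) at a position between two flanking
    bins ``d_left_cM`` / ``d_right_cM`` away (Kosambi-inverted to r).

    Missing flank codes are marginalized; pass ``codes_right=None`` for a
    position with a single usable flank. Rows sum to 1.
    """
    if d_left_cM < 0 or (d_right_cM is not None and d_right_cM < 0):
        raise ValueError("position outside the flanking interval")
    r1 = kosambi_inverse(d_left_cM)
    r2 = None if d_right_cM is None else kosambi_inverse(d_right_cM)
    table = _conditional_table(r1, r2)
    il = np.where(codes_left == MISSING, 3, codes_left).astype(int)
    if codes_right is None:
        ir = np.full(il.shape, 3)
    else:
        ir = np.where(codes_right == MISSING, 3, codes_right).astype(int)
    return table[il, ir]


# ------------------------------------------------------------- scan engine

def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space, robust to collinearity."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if keep.all():
        return q
    # Re-factor the independent subset.
    q2, _ = np.linalg.qr(X[:, keep])
    return q2


@dataclass
class _Position:
    group: int
    cM: float
    q_red: np.ndarray
    q_full: np.ndarray


class _ScanEngine:
    """Precomputed per-position designs so that permutations only cost a
    projection per position."""

    def __init__(self, gmap: GeneticMap, mask: np.ndarray, step: float,
                 cofactors: list[tuple[int, int]] | None = None,
                 window: float = 10.0,
                 include_bin_positions: bool = False):
        self.n = int(mask.sum())
        self.positions: list[_Position] = []
        cof_cols = []
        cof_meta = []  # (group, cM) per cofactor
        if cofactors:
            for gid, b_idx in cofactors:
                grp = gmap.group_by_id(gid)
                codes = grp.bins[b_idx].codes[mask].astype(float)
                x = np.where(codes == MISSING, np.nan, codes - 1.0)
                z = np.where(codes == MISSING, np.nan,
                             (codes == H).astype(float))
                x = np.nan_to_num(x, nan=np.nanmean(x) if np.isfinite(
                    np.nanmean(x)) else 0.0)
                z = np.nan_to_num(z, nan=np.nanmean(z) if np.isfinite(
                    np.nanmean(z)) else 0.0)
                cof_cols.append(np.column_stack([x, z]))
                cof_meta.append((gid, grp.cM_positions[b_idx]))
        ones = np.ones((self.n, 1))
        for grp in gmap.groups:
            cms = np.asarray(grp.cM_positions)
            codes = np.stack([b.codes for b in grp.bins])[:, mask]
            grid = np.arange(0.0, cms[-1] + step / 2.0, step)
            if include_bin_positions:
                grid = np.unique(np.concatenate([grid, cms]))
            for pos in grid:
                probs = _probs_at(codes, cms, float(pos))
                x = probs[:, A] - probs[:, B]
                z = probs[:, H]
                keep_cof = [c for c, (cg, ccm) in zip(cof_cols, cof_meta)
                            if not (cg == grp.id and abs(ccm - pos) < window)]
                base = np.hstack([ones] + keep_cof) if keep_cof else ones
                q_red = _orth_basis(base)
                q_full = _orth_basis(np.column_stack([base, x, z]))
                self.positions.append(_Position(grp.id, float(pos),
                                                q_red, q_full))
        kr = max(p.q_red.shape[1] for p in self.positions)
        kf = max(p.q_full.shape[1] for p in self.positions)
        G = len(self.positions)
        self._QR = np.zeros((G, self.n, kr))
        self._QF = np.zeros((G, self.n, kf))
        for i, p in enumerate(self.positions):
            self._QR[i, :, :p.q_red.shape[1]] = p.q_red
            self._QF[i, :, :p.q_full.shape[1]] = p.q_full

    def profile(self, y: np.ndarray) -> np.ndarray:
        return self.profile_many(y[:, None])[:, 0]

    def profile_many(self, Y: np.ndarray) -> np.ndarray:
        """LOD profiles for each column of ``Y`` (n x P); returns (G x P)."""
        yty = np.sum(Y * Y, axis=0)
        ar = np.tensordot(self._QR, Y, axes=([1], [0]))  # (G, kr, P)
        af = np.tensordot(self._QF, Y, axes=([1], [0]))
        rss0 = np.maximum(yty - np.sum(ar * ar, axis=1), 1e-300)
        rss1 = np.maximum(yty - np.sum(af * af, axis=1), 1e-300)
        lod = (self.n / 2.0) * np.log10(rss0 / rss1)
        return np.maximum(lod, 0.0)

    def frame(self, lod: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "group": [p.group for p in self.positions],
            "cM": [p.cM for p in self.positions],
            "lod": lod})


def _probs_at(codes: np.ndarray, cms: np.ndarray, pos: float) -> np.ndarray:
    """Conditional genotype probabilities at ``pos`` from the nearest
    flanking bins of one group (codes: n_bins x n_ind)."""
    left = int(np.searchsorted(cms, pos, side="right")) - 1
    if left < 0:
        return genotype_probs_f2(codes[0], None, float(cms[0] - pos), None)
    if left >= len(cms) - 1:
        left = len(cms) - 1
        return genotype_probs_f2(codes[left], None,
                                 float(pos - cms[left]), None)
    return genotype_probs_f2(codes[left], codes[left + 1],
                             float(pos - cms[left]),
                             float(cms[left + 1] - pos))


# ------------------------------------------------------------- public ops

@dataclass
class ScanResult:
    trait: str
    method: str
    profile: pd.DataFrame          # columns: group, cM, lod
    step: float
    threshold: float | None = None

    @property
    def max_lod(self) -> float:
        return float(self.profile["lod"].max())


@dataclass
class QTLCall:
    name: str
    trait: str
    group: int
    peak_cM: float
    peak_lod: float
    left_marker: str
    left_cM: float
    right_marker: str
    right_cM: float
    pve: float
    method: str


def _prepare_y(pheno: pd.DataFrame, trait: str,
               individuals: list[str] | None) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype vector aligned to genotype columns plus non-missing mask."""
    if individuals is not None:
        y = pheno[trait].reindex(individuals).to_numpy(dtype=float)
    else:
        y = pheno[trait].to_numpy(dtype=float)
    mask = np.isfinite(y)
    return y[mask], mask


def scan_im(gmap: GeneticMap, pheno: pd.DataFrame, trait: str,
            step: float = 1.0, individuals: list[str] | None = None,
            include_bin_positions: bool = False) -> ScanResult:
    """Interval-mapping LOD profile on a cM grid (default 1 cM walk)."""
    y, mask = _prepare_y(pheno, trait, individuals)
    if y.size < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    engine = _ScanEngine(gmap, mask, step,
                         include_bin_positions=include_bin_positions)
    lod = engine.profile(y)
    return ScanResult(trait, "IM", engine.frame(lod), step)


def permutation_threshold(gmap: GeneticMap, pheno: pd.DataFrame, trait: str,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, step: float = 1.0,
                          cofactors: list[tuple[int, int]] | None = None,
                          window: float = 10.0,
                          individuals: list[str] | None = None) -> float:
    """Genome-wide LOD threshold: the (1 - alpha) quantile of max-LOD over
    ``n_perm`` phenotype permutations. Deterministic given ``seed``."""
    import warnings as _w
    if n_perm < 100:
        _w.warn(f"n_perm={n_perm} is low for a stable threshold",
                stacklevel=2)
    y, mask = _prepare_y(pheno, trait, individuals)
    engine = _ScanEngine(gmap, mask, step, cofactors=cofactors, window=window)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    chunk = 200
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        Y = np.empty((y.size, m))
        for j in range(m):
            Y[:, j] = rng.permutation(y)
        maxima[done:done + m] = engine.profile_many(Y).max(axis=0)
        done += m
    return float(np.quantile(maxima, 1.0 - alpha))


def select_cofactors(gmap: GeneticMap, pheno: pd.DataFrame, trait: str,
                     max_cofactors: int = 5,
                     individuals: list[str] | None = None
                     ) -> list[tuple[int, int]]:
    """Forward selection of background marker cofactors for CIM.

    Bin markers (additive + dominance columns, mean-imputed at missing
    calls) are added greedily by residual-sum-of-squares reduction until
    BIC stops improving or ``max_cofactors`` is reached. Returns
    (group id, bin index) pairs.
    """
    if max_cofactors <= 0:
        return []
    y, mask = _prepare_y(pheno, trait, individuals)
    n = y.size
    candidates: list[tuple[int, int, np.ndarray]] = []
    for grp in gmap.groups:
        for bi, b in enumerate(grp.bins):
            codes = b.codes[mask].astype(float)
            x = np.where(codes == MISSING, np.nan, codes - 1.0)
            z = np.where(codes == MISSING, np.nan, (codes == H).astype(float))
            for col in (x, z):
                mu = np.nanmean(col)
                col[np.isnan(col)] = mu if np.isfinite(mu) else 0.0
            candidates.append((grp.id, bi, np.column_stack([x, z])))
    chosen: list[tuple[int, int]] = []
    design = np.ones((n, 1))
    resid = y - y.mean()
    rss = float(resid @ resid)
    bic = n * np.log(rss / n) + 1 * np.log(n)
    while len(chosen) < max_cofactors:
        best = None
        for gid, bi, cols in candidates:
            if (gid, bi) in chosen:
                continue
            X = np.hstack([design, cols])
            q = _orth_basis(X)
            proj = q.T @ y
            rss_new = max(float(y @ y - proj @ proj), 1e-300)
            if best is None or rss_new < best[0]:
                best = (rss_new, gid, bi, cols)
        if best is None:
            break
        k = design.shape[1] + 2
        bic_new = n * np.log(best[0] / n) + k * np.log(n)
        if bic_new >= bic:
            break
        chosen.append((best[1], best[2]))
        design = np.hstack([design, best[3]])
        bic = bic_new
    return chosen


def scan_cim(gmap: GeneticMap, pheno: pd.DataFrame, trait: str,
             cofactors: list[tuple[int, int]], step: float = 2.0,
             window: float = 10.0,
             individuals: list[str] | None = None,
             include_bin_positions: bool = False) -> ScanResult:
    """Composite interval mapping: IM with background cofactors in both
    models, excluding cofactors within ``window`` cM of the test position
    (default 2 cM walk, 10 cM window)."""
    y, mask = _prepare_y(pheno, trait, individuals)
    if y.size < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    engine = _ScanEngine(gmap, mask, step, cofactors=cofactors, window=window,
                         include_bin_positions=include_bin_positions)
    lod = engine.profile(y)
    return ScanResult(trait, "CIM", engine.frame(lod), step)


def call_qtls(scan: ScanResult, gmap: GeneticMap, pheno: pd.DataFrame,
              individuals: list[str] | None = None) -> list[QTLCall]:
    """One QTL per maximal contiguous super-threshold region.

    Peak = argmax LOD in the region; the flanking markers are the nearest
    bins bounding the region; PVE is the coefficient of determination of
    the additive + dominance regression at the bin marker nearest the peak
    (complete-case at that bin).
    """
    if scan.threshold is None:
        raise ValueError("scan has no threshold; run permutation_threshold")
    y_all, mask = _prepare_y(pheno, scan.trait, individuals)
    calls: list[QTLCall] = []
    counter: dict[int, int] = {}
    for gid, sub in scan.profile.groupby("group", sort=False):
        grp = gmap.group_by_id(gid)
        cms = np.asarray(grp.cM_positions)
        above = (sub["lod"] > scan.threshold).to_numpy()
        pos = sub["cM"].to_numpy()
        lod = sub["lod"].to_numpy()
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            peak_idx = i + int(np.argmax(lod[seg]))
            start, end = pos[i], pos[j]
            li = int(np.searchsorted(cms, start, side="right")) - 1
            li = max(li, 0)
            ri = int(np.searchsorted(cms, end, side="left"))
            ri = min(ri, len(cms) - 1)
            near = int(np.argmin(np.abs(cms - pos[peak_idx])))
            pve = _marker_pve(grp.bins[near].codes[mask], y_all)
            counter[gid] = counter.get(gid, 0) + 1
            calls.append(QTLCall(
                name=f"qSC{scan.trait}{gid}.{counter[gid]}",
                trait=scan.trait, group=gid,
                peak_cM=float(pos[peak_idx]), peak_lod=float(lod[peak_idx]),
                left_marker=grp.bins[li].marker_id, left_cM=float(cms[li]),
                right_marker=grp.bins[ri].marker_id, right_cM=float(cms[ri]),
                pve=pve, method=scan.method))
            i = j + 1
    return calls


def _marker_pve(codes: np.ndarray, y: np.ndarray) -> float:
    ok = codes != MISSING
    if ok.sum() < 3:
        return float("nan")
    g = codes[ok].astype(float)
    yy = y[ok]
    X = np.column_stack([np.ones(ok.sum()), g - 1.0, (g == H).astype(float)])
    q = _orth_basis(X)
    proj = q.T @ yy
    yc = yy - yy.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        return float("nan")
    rss = max(float(yy @ yy - proj @ proj), 0.0)
    return float(max(0.0, min(1.0, 1.0 - rss / tss)))


def qtls_to_dataframe(calls: list[QTLCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": c.trait, "group": c.group, "qtl": c.name,
        "left_marker": c.left_marker, "left_cM": round(c.left_cM, 2),
        "right_marker": c.right_marker, "right_cM": round(c.right_cM, 2),
        "pve_pct": round(100.0 * c.pve, 2), "peak_cM": round(c.peak_cM, 2),
        "peak_lod": round(c.peak_lod, 2), "method": c.method}
        for c in calls])


# ----------------------------------------------------------- model facade

class QTLScanModel:
    """Statsmodels-style front end to the scan operations.

    Parameters
    ----------
    gmap : spaced GeneticMap
    pheno : DataFrame indexed by individual name, one column per trait
    trait : column to scan
    method : "im" or "cim"
    individuals : genotype column order; defaults to the phenotype row order
    """

    def __init__(self, gmap: GeneticMap, pheno: pd.DataFrame, trait: str,
                 method: str = "im", step: float | None = None,
                 cim_window: float = 10.0, max_cofactors: int = 5,
                 individuals: list[str] | None = None):
        method = method.lower()
        if method not in ("im", "cim"):
            raise ValueError("method must be 'im' or 'cim'")
        self.gmap = gmap
        self.pheno = pheno
        self.trait = trait
        self.method = method
        self.step = step if step is not None else (1.0 if method == "im" else 2.0)
        self.cim_window = cim_window
        self.max_cofactors = max_cofactors
        self.individuals = individuals

    def fit(self, n_perm: int = 1000, alpha: float = 0.05,
            seed: int = 0) -> "QTLScanResults":
        cofactors = None
        if self.method == "cim":
            cofactors = select_cofactors(self.gmap, self.pheno, self.trait,
                                         self.max_cofactors,
                                         individuals=self.individuals)
            scan = scan_cim(self.gmap, self.pheno, self.trait, cofactors,
                            step=self.step, window=self.cim_window,
                            individuals=self.individuals)
        else:
            scan = scan_im(self.gmap, self.pheno, self.trait, step=self.step,
                           individuals=self.individuals)
        scan.threshold = permutation_threshold(
            self.gmap, self.pheno, self.trait, n_perm=n_perm, alpha=alpha,
            seed=seed, step=self.step, cofactors=cofactors,
            window=self.cim_window, individuals=self.individuals)
        calls = call_qtls(scan, self.gmap, self.pheno,
                          individuals=self.individuals)
        return QTLScanResults(self, scan, calls, cofactors or [])


@dataclass
class QTLScanResults:
    model: QTLScanModel
    scan: ScanResult
    qtls: list[QTLCall]
    cofactors: list[tuple[int, int]] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.scan.threshold

    def qtl_frame(self) -> pd.DataFrame:
        return qtls_to_dataframe(self.qtls)

    def summary(self) -> str:
        lines = [
            f"QTL scan summary — trait {self.scan.trait} "
            f"({self.scan.method}, step {self.scan.step} cM)",
            f"Positions scanned: {len(self.scan.profile)}   "
            f"max LOD: {self.scan.max_lod:.2f}   "
            f"threshold: {self.threshold:.2f}",
            f"QTLs above threshold: {len(self.qtls)}",
        ]
        if self.qtls:
            lines.append(self.qtl_frame().to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD profile with the permutation threshold, one panel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        offset = 0.0
        for gid, sub in self.scan.profile.groupby("group", sort=False):
            ax.plot(sub["cM"] + offset, sub["lod"], lw=1.0,
                    label=f"LG{gid}")
            offset += sub["cM"].max() + 5.0
        ax.axhline(self.threshold, color="red", ls="--", lw=0.8,
                   label="threshold")
        ax.set_xlabel("map position (cM, groups concatenated)")
        ax.set_ylabel("LOD")
        ax.set_title(f"{self.scan.trait} ({self.scan.method})")
        ax.legend(fontsize=7, ncol=4)
        return ax
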