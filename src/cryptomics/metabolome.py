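"""MALDI-MSI-style spectrum statistics: peak picking, isotope exclusion,
discriminative-mass testing, ppm annotation, pathway topology enrichment,
Ward clustering.

Peak picking follows a LIMPIC-style recipe on the mean spectrum: local
maxima whose above-half-maximum support spans at least a minimal m/z width
are kept if their signal-to-noise ratio (height over a robust MAD noise
estimate of the detrended mean spectrum) reaches ``snr_min`` and their
height clears a relative intensity threshold.  Defaults mirror FT-ICR
negative-mode metabolite imaging practice: minimal width 0.0005 m/z,
SNR 4, intensity threshold 0.01% of the global maximum, annotation at
<= 4 ppm, and significance at fold change >= 2 with two-tailed t-test
P <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
import scipy.ndimage as ndi
import scipy.stats as st

from .core import ValidationError
from .simulate import ISOTOPE_SPACING, SpectrumSet

__all__ = [
    "pick_peaks",
    "exclude_isotopes",
    "discriminative_masses",
    "annotate_masses",
    "pathway_enrichment",
    "ward_cluster",
]


def detrend_spectrum(mean_spectrum: np.ndarray, window: int = 51) -> np.ndarray:
    """Baseline-subtracted mean spectrum (median filter removes peaks and
    slow baseline; peak heights are measured above this baseline)."""
    baseline = ndi.median_filter(mean_spectrum, size=window, mode="nearest")
    return mean_spectrum - baseline


def estimate_noise_sigma(detrended: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * MAD of the detrended mean spectrum."""
    mad = np.median(np.abs(detrended - np.median(detrended)))
    return float(1.4826 * mad)


def pick_peaks(
    spectra: SpectrumSet,
    min_width: float = 0.0005,
    snr_min: float = 4.0,
    intensity_frac: float = 0.0001,
    noise_window: int = 501,
) -> pd.DataFrame:
    """Pick peaks on the baseline-subtracted mean spectrum.

    The mean spectrum is detrended with a running median (window
    ``noise_window`` grid points, wider than any peak) and heights are
    measured above that baseline.  A local maximum is a peak when (i) the
    contiguous region around it that stays above half its height spans
    >= ``min_width`` in m/z, (ii) its height over the noise sigma is
    >= ``snr_min``, and (iii) its height is >= ``intensity_frac`` times
    the global maximum of the detrended mean spectrum.
    Per-sample intensity is the maximum within the peak's half-height
    support.  Thresholds are relative, so rescaling all spectra by a
    constant leaves the peak set unchanged.
    """
    mz = spectra.mz
    if mz.size < 3:
        raise ValidationError("grid too short for peak picking")
    max_step = float(np.max(np.diff(mz)))
    if max_step > min_width:
        raise ValidationError(
            f"grid spacing {max_step:g} coarser than min_width {min_width:g}; "
            "peaks of minimal width are undetectable"
        )
    mean = detrend_spectrum(spectra.mean_spectrum(), window=noise_window)
    sigma = estimate_noise_sigma(mean)
    global_max = float(mean.max())
    # interior local maxima (plateaus: first point of the plateau)
    rising = np.r_[False, mean[1:] > mean[:-1]]
    falling = np.r_[mean[:-1] > mean[1:], False]
    apex_idx = np.flatnonzero(rising & falling)

    rows = []
    for i in apex_idx:
        h = mean[i]
        if global_max > 0 and h < intensity_frac * global_max:
            continue
        if sigma > 0 and h / sigma < snr_min:
            continue
        half = h / 2.0
        lo = i
        while lo > 0 and mean[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi < mz.size - 1 and mean[hi + 1] >= half:
            hi += 1
        width = mz[hi] - mz[lo]
        if width < min_width:
            continue
        support = slice(lo, hi + 1)
        rows.append(
            {
                "mz": float(mz[i]),
                "height": float(h),
                "snr": float(h / sigma) if sigma > 0 else np.inf,
                "width": float(width),
                "support_lo": float(mz[lo]),
                "support_hi": float(mz[hi]),
                **{
                    f"intensity_{j}": float(spectra.intensities[j, support].max())
                    for j in range(spectra.intensities.shape[0])
                },
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("mz").reset_index(drop=True)
        table["isotope"] = False
    table.attrs["noise_sigma"] = sigma
    table.attrs["groups"] = list(spectra.groups)
    return table


def _intensity_cols(peaks: pd.DataFrame) -> list[str]:
    return [c for c in peaks.columns if c.startswith("intensity_")]


def exclude_isotopes(
    peaks: pd.DataFrame,
    delta: float = ISOTOPE_SPACING,
    tol_ppm: float = 20.0,
    max_ratio: float = 1.0,
) -> pd.DataFrame:
    """Flag and remove isotope satellites.

    A peak is an isotope when some other peak sits ``delta`` below it
    (within ``tol_ppm``) and the candidate's mean intensity is at most
    ``max_ratio`` times that peak's.  Matching is against *all* peaks, so
    chains cascade: M+2 is removed relative to M+1 even though M+1 is
    itself removed relative to M.
    """
    if not len(peaks):
        return peaks.copy()
    cols = _intensity_cols(peaks)
    mean_int = (
        peaks[cols].mean(axis=1).values if cols else peaks["height"].values
    )
    mzs = peaks["mz"].values
    is_iso = np.zeros(len(peaks), dtype=bool)
    for i in range(len(peaks)):
        target = mzs[i] - delta
        tol = tol_ppm * 1e-6 * mzs[i]
        cand = np.flatnonzero(np.abs(mzs - target) <= tol)
        for j in cand:
            if j != i and mean_int[i] <= max_ratio * mean_int[j]:
                is_iso[i] = True
                break
    out = peaks.copy()
    out["isotope"] = is_iso
    kept = out.loc[~is_iso].reset_index(drop=True)
    kept.attrs.update(peaks.attrs)
    kept.attrs["n_isotopes_removed"] = int(is_iso.sum())
    return kept


def discriminative_masses(
    peaks: pd.DataFrame,
    groups: list[str] | None = None,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Group-discriminating peaks: fold change >= ``fc_min`` and two-tailed
    t-test P <= ``p_max``.

    FC is larger group mean over smaller; direction records whether the
    second group is enriched or depleted relative to the first.  Pooled-
    variance (Student) t by default, Welch behind ``welch=True``.
    """
    groups = list(groups if groups is not None else peaks.attrs.get("groups", []))
    cols = _intensity_cols(peaks)
    if len(groups) != len(cols):
        raise ValidationError("one group label per intensity column required")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, found {levels}")
    g = np.array(groups)
    i1, i2 = np.flatnonzero(g == levels[0]), np.flatnonzero(g == levels[1])
    if len(i1) < 2 or len(i2) < 2:
        raise ValidationError("need >= 2 samples per group")
    X = peaks[cols].values
    x1, x2 = X[:, i1], X[:, i2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    t, p = st.ttest_ind(x1, x2, axis=1, equal_var=not welch)
    hi, lo = np.maximum(m1, m2), np.minimum(m1, m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.inf)
    out = peaks[["mz"]].copy()
    out[f"mean_{levels[0]}"] = m1
    out[f"mean_{levels[1]}"] = m2
    out["fc"] = fc
    out["t"] = t
    out["P"] = p
    out["direction"] = np.where(m2 >= m1, "enriched", "depleted")
    out["pass"] = (fc >= fc_min) & (out["P"].values <= p_max)
    out.attrs["n_pass"] = int(out["pass"].sum())
    out.attrs["n_enriched"] = int((out["pass"] & (out["direction"] == "enriched")).sum())
    out.attrs["n_depleted"] = int((out["pass"] & (out["direction"] == "depleted")).sum())
    return out


def annotate_masses(
    peaks: pd.DataFrame, metabolite_db: pd.DataFrame, ppm_max: float = 4.0
) -> pd.DataFrame:
    """Annotate peaks against a metabolite database by accurate mass.

    Every database entry within ``ppm_max`` relative error of a peak's m/z
    is retained, sorted by ppm error.  Adduct adjustment is expected to
    have been applied to the database masses upstream.
    """
    if metabolite_db is None or not len(metabolite_db):
        raise ValidationError("empty metabolite database")
    db_mass = metabolite_db["exact_mass"].values.astype(float)
    db_id = metabolite_db["id"].astype(str).values
    annotations = []
    for mz in peaks["mz"].values:
        ppm = np.abs(mz - db_mass) / db_mass * 1e6
        hit = np.flatnonzero(ppm <= ppm_max)
        hit = hit[np.argsort(ppm[hit], kind="stable")]
        annotations.append(
            ";".join(f"{db_id[j]}:{ppm[j]:.2f}" for j in hit)
        )
    out = peaks.copy()
    out["annotation"] = annotations
    out["annotated"] = [a != "" for a in annotations]
    out.attrs.update(peaks.attrs)
    return out


def pathway_enrichment(
    hits: set[str] | list[str],
    pathway_graph: dict,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric pathway over-representation with a topology impact.

    P = upper-tail hypergeometric of the hit/pathway overlap; impact = the
    summed relative betweenness centrality of hit nodes within the pathway
    graph (node betweenness / total betweenness over pathway nodes), a
    value in [0, 1].  Singleton pathways get impact 1 if hit else 0; a
    pathway whose betweenness is everywhere zero falls back to the hit
    fraction of nodes.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValidationError("hit metabolites must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for pw, entry in pathway_graph.items():
        nodes = [n for n in entry["nodes"] if n in universe]
        if not nodes:
            continue
        n = len(nodes)
        k = len(set(nodes) & hits)
        p = float(st.hypergeom.sf(k - 1, M, n, N))
        if n == 1:
            impact = 1.0 if k == 1 else 0.0
        else:
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(
                (a, b) for a, b in entry.get("edges", [])
                if a in g and b in g
            )
            btw = nx.betweenness_centrality(g, normalized=False)
            total = sum(btw.values())
            if total > 0:
                impact = sum(btw[m] for m in set(nodes) & hits) / total
            else:
                impact = k / n
        rows.append(
            {
                "pathway": pw,
                "n_pathway": n,
                "n_overlap": k,
                "P": p,
                "impact": impact,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("P").reset_index(drop=True)
    return out


def ward_cluster(features: np.ndarray) -> np.ndarray:
    """Agglomerative Ward clustering via Lance-Williams updates.

    Returns a linkage-style merge list: each row (i, j, height, size) with
    i < j referring to original rows 0..n-1 and merged clusters n, n+1, ...
    in merge order.  Distances are Euclidean; ties break toward the
    smallest pair of cluster indices.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 rows to cluster")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in feature matrix")
    n = X.shape[0]
    # squared Euclidean distances between active clusters
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    index = {i: i for i in range(n)}  # cluster id -> row in d2
    Z = np.empty((n - 1, 4))
    next_id = n
    d2 = d2.astype(float)
    for step in range(n - 1):
        # find minimal Ward distance among active pairs; ties -> smallest ids
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                val = d2[index[a], index[b]]
                if best is None or val < best[0] - 1e-15:
                    best = (val, a, b)
        _, a, b = best
        na, nb = sizes[a], sizes[b]
        height = float(np.sqrt(d2[index[a], index[b]]))
        Z[step] = (a, b, height, na + nb)
        # Lance-Williams Ward update on squared distances
        ia, ib = index[a], index[b]
        for c in active:
            if c in (a, b):
                continue
            ic = index[c]
            nc = sizes[c]
            d2_new = (
                (na + nc) * d2[ia, ic] + (nb + nc) * d2[ib, ic] - nc * d2[ia, ib]
            ) / (na + nb + nc)
            d2[ia, ic] = d2[ic, ia] = d2_new
        # merged cluster reuses row ia
        active.remove(a)
        active.remove(b)
        sizes[next_id] = na + nb
        index[next_id] = ia
        active.append(next_id)
        active.sort()
        next_id += 1
    return Z
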