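"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package implementations: the
prominence oracle floods superlevel sets per candidate maximum with
repeated connected-component labeling; the Otsu oracle loops over every
cut point computing class statistics directly from the pixel values; the
volume-bin oracle assigns elements one at a time.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

_EIGHT = np.ones((3, 3), dtype=bool)


def prominence_maxima_oracle(image, mask=None):
    """All local-maximum plateaus with their prominences.

    Returns a list of ((row, col), prominence) where the representative is
    the topmost-then-leftmost plateau pixel.  Prominence is the peak height
    above the highest superlevel at which the maximum's component contains
    a strictly higher pixel; if no higher pixel exists in its mask
    component, the component minimum is used instead.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    out = []
    visited = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or visited[r, c]:
                continue
            val = img[r, c]
            plateau_lab, _ = ndi.label((img == val) & mask, structure=_EIGHT)
            plateau = plateau_lab == plateau_lab[r, c]
            visited |= plateau
            border = ndi.binary_dilation(plateau, structure=_EIGHT) & mask & ~plateau
            if border.any() and img[border].max() > val:
                continue  # not a local maximum
            prominence = None
            levels = np.unique(img[mask])
            for v in levels[levels <= val][::-1]:
                sup_lab, _ = ndi.label((img >= v) & mask, structure=_EIGHT)
                comp = sup_lab == sup_lab[r, c]
                if img[comp].max() > val:
                    prominence = val - v
                    break
            if prominence is None:
                comp_lab, _ = ndi.label(mask, structure=_EIGHT)
                comp = comp_lab == comp_lab[r, c]
                prominence = val - img[comp].min()
            rows, cols = np.nonzero(plateau)
            i = np.lexsort((cols, rows))[0]
            out.append(((int(rows[i]), int(cols[i])), float(prominence)))
    return out


def accepted_maxima_oracle(image, mask, tolerance):
    """Accepted (row, col) calls at one tolerance, sorted."""
    return sorted(rep for rep, prom in prominence_maxima_oracle(image, mask)
                  if prom > tolerance)


def otsu_oracle(pixels):
    """Exhaustive Otsu: per-cut class statistics from raw values; the
    returned threshold assigns values <= t to background; ties to lowest."""
    vals = np.asarray(pixels, dtype=np.int64).ravel()
    best_t, best_score = None, -1.0
    for t in range(int(vals.max()) + 1):
        bg = vals[vals <= t]
        fg = vals[vals > t]
        if bg.size == 0 or fg.size == 0:
            continue
        score = bg.size * fg.size * (bg.mean() - fg.mean()) ** 2
        if score > best_score:
            best_score, best_t = score, t
    return best_t


def volume_bin_oracle(volumes, bounds=(100.0, 1000.0)):
    """Per-element bin assignment summed one at a time."""
    lo, hi = bounds
    sums = {"small": 0.0, "medium": 0.0, "large": 0.0}
    for v in volumes:
        if v < lo:
            sums["small"] += v
        elif v <= hi:
            sums["medium"] += v
        else:
            sums["large"] += v
    total = sum(sums.values())
    return tuple(100.0 * sums[k] / total for k in ("small", "medium", "large"))


def beer_lambert_oracle(slope_au_per_min, epsilon, path_cm, protein_mg,
                        volume_ml=1.0):
    """Dimensional-analysis chain, written step by step.

    AU/min over epsilon*path gives mol L^-1 min^-1; times volume in L
    gives mol/min; times 1e9 gives nmol/min; per mg protein.
    """
    conc_rate_molar = abs(slope_au_per_min) / (epsilon * path_cm)
    mol_per_min = conc_rate_molar * volume_ml * 1e-3
    nmol_per_min = mol_per_min * 1e9
    return nmol_per_min / protein_mg
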