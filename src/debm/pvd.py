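"""Bootstrap positional variance of the event ordering.

Uncertainty in the estimated sequence is quantified by resampling subjects
with replacement — stratified by their role (reference / disease / held
out), so every replicate preserves the two-population premise of the
mixtures — then refitting the per-biomarker mixtures and re-estimating the
ordering.  The event set and abnormality directions stay fixed from the
full-data fit.  The resulting events x positions count matrix (rows sorted
by the full-data ordering) is the positional variance diagram: a dark
diagonal means a confident sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ebm import EventOrdering, estimate_ordering
from .mixture import BiomarkerMixture, fit_mixture


@dataclass
class PositionalVariance:
    """Events x positions bootstrap count matrix."""

    counts: pd.DataFrame  # rows: events sorted by the full-data ordering; cols 1..N
    n_bootstraps: int
    reference_ordering: tuple[str, ...]

    def check_conservation(self) -> None:
        """Every row and column must sum to the number of bootstraps."""
        rows = self.counts.sum(axis=1)
        cols = self.counts.sum(axis=0)
        if not ((rows == self.n_bootstraps).all() and (cols == self.n_bootstraps).all()):
            raise AssertionError("PVD conservation violated: a bootstrap lost a permutation")

    def positional_entropy(self) -> pd.Series:
        """Shannon entropy (nats) of each event's position distribution."""
        p = self.counts.to_numpy(float) / self.n_bootstraps
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
        return pd.Series(h, index=self.counts.index, name="entropy")


def _fit_replicate_mixtures(zmat: pd.DataFrame, events, disease_pos, reference_pos,
                            directions: dict[str, str]) -> dict[str, BiomarkerMixture]:
    vals = zmat[list(events)].to_numpy(float)
    mixtures = {}
    for j, e in enumerate(events):
        d = vals[disease_pos, j]
        d = d[~np.isnan(d)]
        r = vals[reference_pos, j]
        r = r[~np.isnan(r)]
        mixtures[e] = fit_mixture(d, r if len(r) else None, directions[e])
    return mixtures


def _posteriors_at(zmat: pd.DataFrame, events, positions,
                   mixtures: dict[str, BiomarkerMixture]) -> np.ndarray:
    vals = zmat[list(events)].to_numpy(float)[positions]
    P = np.empty_like(vals)
    for j, e in enumerate(events):
        P[:, j] = mixtures[e].posterior_abnormal(vals[:, j])
    return P


def bootstrap_pvd(zmat: pd.DataFrame, events, roles: dict[str, np.ndarray],
                  directions: dict[str, str], B: int = 1000, seed: int | None = None,
                  full_ordering: EventOrdering | None = None,
                  max_retries: int = 10) -> PositionalVariance:
    """Bootstrap the ordering B times and accumulate positional counts.

    Parameters
    ----------
    zmat : DataFrame of z-scores, one row per subject (position-indexed here).
    events : the fixed, post-selection event list.
    roles : mapping with integer row positions for "reference", "disease"
        and optionally "held_out" subjects.  Disease + held-out rows enter
        the posterior matrix and the ordering; reference rows anchor the
        mixtures.
    directions : per-event abnormality direction, fixed from the full data.
    full_ordering : the full-data ordering used to sort the rows of the
        count matrix; estimated here if not supplied.
    """
    events = list(events)
    N = len(events)
    rng = np.random.default_rng(seed)
    ref_pos = np.asarray(roles.get("reference", []), dtype=int)
    dis_pos = np.asarray(roles["disease"], dtype=int)
    held_pos = np.asarray(roles.get("held_out", []), dtype=int)

    if full_ordering is None:
        mix_full = _fit_replicate_mixtures(zmat, events, dis_pos, ref_pos, directions)
        order_pos = np.concatenate([dis_pos, held_pos]).astype(int)
        P_full = _posteriors_at(zmat, events, order_pos, mix_full)
        full_ordering = estimate_ordering(pd.DataFrame(P_full, columns=events))

    counts = pd.DataFrame(0, index=pd.Index(full_ordering.events, name="event"),
                          columns=pd.RangeIndex(1, N + 1, name="position"), dtype=int)

    for _ in range(B):
        for attempt in range(max_retries + 1):
            ref_b = rng.choice(ref_pos, size=len(ref_pos)) if len(ref_pos) else ref_pos
            dis_b = rng.choice(dis_pos, size=len(dis_pos))
            held_b = rng.choice(held_pos, size=len(held_pos)) if len(held_pos) else held_pos
            try:
                mix_b = _fit_replicate_mixtures(zmat, events, dis_b, ref_b, directions)
                order_rows = np.concatenate([dis_b, held_b]).astype(int)
                P_b = _posteriors_at(zmat, events, order_rows, mix_b)
                ordering_b = estimate_ordering(pd.DataFrame(P_b, columns=events))
                break
            except ValueError:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"bootstrap replicate failed after {max_retries} redraws")
        for pos, e in enumerate(ordering_b.events, start=1):
            counts.loc[e, pos] += 1

    pv = PositionalVariance(counts=counts, n_bootstraps=B,
                            reference_ordering=tuple(full_ordering.events))
    pv.check_conservation()
    return pv


def render_pvd(pv: PositionalVariance, cap: int = 500, png_path=None, tsv_path=None,
               title: str | None = None):
    """Heatmap of bootstrap counts, intensity capped for visualisation.

    The TSV written alongside always holds the uncapped counts.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    capped = np.minimum(pv.counts.to_numpy(), cap)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.4 * len(pv.counts))))
    ax.imshow(capped, cmap="Blues", aspect="auto", vmin=0, vmax=cap)
    ax.set_yticks(range(len(pv.counts.index)))
    ax.set_yticklabels(pv.counts.index)
    ax.set_xticks(range(len(pv.counts.columns)))
    ax.set_xticklabels(pv.counts.columns)
    ax.set_xlabel("event position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if png_path is not None:
        fig.savefig(png_path, dpi=150)
    if tsv_path is not None:
        pv.counts.to_csv(tsv_path, sep="\t")
    return fig
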