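"""Dufrene-Legendre indicator value (IndVal) analysis with a permutation null.

For a two-group design (here: 0.1% vs 1% CH4 headspace within a grazing
treatment), the indicator value of OTU i for group j is

    IndVal_ij = A_ij * B_ij

with specificity A_ij = mean abundance of i in j divided by the summed
group means, and fidelity B_ij = fraction of group-j samples where i is
present. The per-OTU statistic is the maximum IndVal across groups, tested
by shuffling group labels. OTUs significant at alpha are "responding
bioindicators"; those consistent across (or exclusive to) grazing
treatments are "unconditional bioindicators".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gas_kinetics import ValidationError

PEAT_SOIL_INDEPENDENT = "peat soil independent"


def _group_matrix(labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """One-hot groups x samples matrix."""
    return (labels[None, :] == groups[:, None]).astype(float)


def _indval_components(X: np.ndarray, onehot: np.ndarray):
    """A (specificity), B (fidelity) and IndVal, each groups x OTUs."""
    sizes = onehot.sum(axis=1)
    group_means = (onehot @ X) / sizes[:, None]
    totals = group_means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(totals > 0, group_means / totals, 0.0)
    B = (onehot @ (X > 0)) / sizes[:, None]
    return A, B, A * B


@dataclass
class IndValResult:
    """Per-OTU indicator values for a two-group community matrix."""

    A: pd.DataFrame            # OTUs x groups specificity
    B: pd.DataFrame            # OTUs x groups fidelity
    indval: pd.DataFrame       # OTUs x groups indicator value
    best_group: pd.Series      # per OTU
    stat: pd.Series            # max IndVal per OTU
    p_values: pd.Series | None = None

    @property
    def groups(self) -> list:
        return list(self.indval.columns)


def indval(abundance: pd.DataFrame, labels) -> IndValResult:
    """Indicator values of every OTU for every group.

    abundance: samples x OTUs (raw or relative); labels: one group label
    per sample, every group with at least two samples.
    """
    labels = np.asarray(labels)
    if len(labels) != abundance.shape[0]:
        raise ValidationError("one group label per sample is required")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if counts.min() < 2:
        raise ValidationError("every group needs at least two samples")
    X = abundance.to_numpy(dtype=float)
    A, B, iv = _indval_components(X, _group_matrix(labels, groups))
    otus = abundance.columns
    ivd = pd.DataFrame(iv.T, index=otus, columns=groups)
    best = ivd.idxmax(axis=1)
    return IndValResult(
        A=pd.DataFrame(A.T, index=otus, columns=groups),
        B=pd.DataFrame(B.T, index=otus, columns=groups),
        indval=ivd,
        best_group=best,
        stat=ivd.max(axis=1),
    )


def permutation_pvalues(
    abundance: pd.DataFrame,
    labels,
    n_permutations: int = 10_000,
    seed: int | None = None,
    comparison: str = "ge",
    plus_one: bool = True,
    chunk: int = 500,
) -> IndValResult:
    """IndVal with permutation p-values for every OTU.

    The per-OTU statistic is its maximum IndVal across groups; group
    labels are shuffled uniformly n_permutations times and

        p = (#{permuted stat >= observed} + 1) / (n_permutations + 1)

    (comparison="gt" and plus_one=False select the alternative readings).
    Fixed seed gives bit-identical p-values.
    """
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    if comparison not in ("ge", "gt"):
        raise ValidationError("comparison must be 'ge' or 'gt'")
    result = indval(abundance, labels)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    X = abundance.to_numpy(dtype=float)
    presence = (X > 0).astype(float)
    observed = result.stat.to_numpy()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1], dtype=np.int64)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        # permuted one-hot matrices, shape (m, n_groups, n_samples)
        perm_labels = np.array([rng.permutation(labels) for _ in range(m)])
        onehot = (perm_labels[:, None, :] == groups[None, :, None]).astype(float)
        sizes = onehot.sum(axis=2)                      # m x groups
        means = onehot @ X / sizes[:, :, None]          # m x groups x otus
        totals = means.sum(axis=1)                      # m x otus
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(totals[:, None, :] > 0, means / totals[:, None, :], 0.0)
        B = onehot @ presence / sizes[:, :, None]
        stat = (A * B).max(axis=1)                      # m x otus
        if comparison == "ge":
            exceed += (stat >= observed[None, :]).sum(axis=0)
        else:
            exceed += (stat > observed[None, :]).sum(axis=0)
        done += m
    if plus_one:
        p = (exceed + 1) / (n_permutations + 1)
    else:
        p = exceed / n_permutations
        p = np.maximum(p, 1.0 / n_permutations)  # avoid exact zeros
    result.p_values = pd.Series(p, index=abundance.columns)
    return result


def responding_bioindicators(result: IndValResult, alpha: float = 0.01) -> pd.DataFrame:
    """OTUs significant at alpha, labeled by their best group.

    Returns a frame indexed by OTU with columns group, indval, p.
    """
    if result.p_values is None:
        raise ValidationError("run permutation_pvalues before selecting bioindicators")
    sel = result.p_values[result.p_values < alpha]
    return pd.DataFrame(
        {
            "group": result.best_group.loc[sel.index],
            "indval": result.stat.loc[sel.index],
            "p": sel,
        }
    )


def unconditional_bioindicators(
    grazed: pd.DataFrame,
    exclosed: pd.DataFrame,
    grazed_abundance: pd.DataFrame,
    exclosed_abundance: pd.DataFrame,
) -> pd.DataFrame:
    """Combine per-treatment responding bioindicators into the unconditional set.

    Criterion 1: the OTU responds to the same CH4 level in both grazed and
    exclosed microcosms (labeled "peat soil independent"). Criterion 2: it
    responds in one treatment and is absent (zero abundance in every
    sample, post-denoising) from the other (labeled by the treatment where
    it responds). Both treatments must share the same OTU space.
    """
    if set(grazed_abundance.columns) != set(exclosed_abundance.columns):
        raise ValidationError("grazed and exclosed tables must share one OTU space")
    absent_grazed = set(grazed_abundance.columns[(grazed_abundance == 0).all(axis=0)])
    absent_exclosed = set(exclosed_abundance.columns[(exclosed_abundance == 0).all(axis=0)])
    rows = []
    seen = set()
    for otu in grazed.index:
        level = grazed.loc[otu, "group"]
        if otu in exclosed.index and exclosed.loc[otu, "group"] == level:
            rows.append({"otu": otu, "ch4_level": level, "criterion": 1,
                         "label": PEAT_SOIL_INDEPENDENT})
            seen.add(otu)
        elif otu in absent_exclosed:
            rows.append({"otu": otu, "ch4_level": level, "criterion": 2,
                         "label": "grazed"})
            seen.add(otu)
    for otu in exclosed.index:
        if otu in seen:
            continue
        level = exclosed.loc[otu, "group"]
        if otu in absent_grazed:
            rows.append({"otu": otu, "ch4_level": level, "criterion": 2,
                         "label": "exclosed"})
    return pd.DataFrame(rows, columns=["otu", "ch4_level", "criterion", "label"]).set_index("otu")


def export_long(result: IndValResult, responding: pd.DataFrame | None = None) -> pd.DataFrame:
    """Heatmap-ready long-format export (otu, group, indval, A, B, p, flags)."""
    records = []
    for otu in result.indval.index:
        for group in result.groups:
            records.append(
                {
                    "otu": otu,
                    "group": group,
                    "indval": result.indval.loc[otu, group],
                    "A": result.A.loc[otu, group],
                    "B": result.B.loc[otu, group],
                    "best_group": result.best_group.loc[otu] == group,
                    "p": None if result.p_values is None else result.p_values.loc[otu],
                    "responding": responding is not None
                    and otu in responding.index
                    and responding.loc[otu, "group"] == group,
                }
            )
    return pd.DataFrame(records)
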