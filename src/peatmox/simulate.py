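"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its arguments and seed, and returns
the simulated object together with a truth record sufficient to score the
downstream analysis stage: exponential headspace CH4 decay with
multiplicative measurement noise (GC error scales with concentration),
Dirichlet-multinomial two-group OTU tables with planted
concentration-responsive taxa, pmoA-like open reading frames and amplicon
reads with planted stop-codon/frameshift/low-quality defects, log-linear
qPCR dilution series, and Jukes-Cantor sequence evolution along a known
tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import AmpliconRead, OTUTable, STOP_CODONS
from .gas_kinetics import (
    DEFAULT_HENRY,
    BottleSpec,
    GasTimeSeries,
    HenryParams,
    ValidationError,
    dissolved_ch4,
    headspace_moles,
    total_ch4_mass,
)
from .phylogeny import Alignment
from .qpcr import DEFAULT_STANDARD_LEVELS, DilutionStandard

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _removal_share(bottle: BottleSpec, gas_ml: float, liquid_ml: float,
                   henry: HenryParams) -> float:
    gas_unit = headspace_moles(bottle, 1.0)
    diss_unit = (
        dissolved_ch4(1.0, bottle.temperature, henry, bottle.pressure)
        * bottle.liquid_volume / 1000.0
        if bottle.liquid_volume > 0
        else 0.0
    )
    f_gas = gas_ml / bottle.headspace_volume
    f_liq = liquid_ml / bottle.liquid_volume if bottle.liquid_volume > 0 else 0.0
    return (gas_unit * f_gas + diss_unit * f_liq) / (gas_unit + diss_unit)


def gen_gas_series(
    k: float,
    c0: float,
    times,
    noise_sd: float = 0.0,
    bottle: BottleSpec | None = None,
    seed: int | None = None,
    gas_sample_volume: float = 0.0,
    liquid_sample_volume: float = 0.0,
    sampling_losses: bool = False,
    henry: HenryParams = DEFAULT_HENRY,
) -> tuple[GasTimeSeries, dict]:
    """First-order CH4 decay C(t) = c0 exp(-k t) (1 + eps), eps ~ N(0, sd).

    With sampling_losses=True each measurement additionally removes the
    stated gas/liquid volumes' share of CH4 from the bottle, so the
    recorded decline mixes oxidation and withdrawal (the regime the
    sampling-correction step undoes). k = 0 with sampling losses gives a
    series declining by withdrawal alone.
    """
    if k < 0:
        raise ValidationError("rate constant must be non-negative")
    if c0 <= 0:
        raise ValidationError("initial mixing ratio must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    bottle = bottle or BottleSpec(total_volume=50.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    if sampling_losses:
        share = _removal_share(bottle, gas_sample_volume, liquid_sample_volume, henry)
        mass_per_ppm = total_ch4_mass(bottle, 1.0, henry)
        m = c0 * mass_per_ppm
        clean = np.empty_like(times)
        for i, t in enumerate(times):
            if i > 0:
                m *= np.exp(-k * (times[i] - times[i - 1]))
            clean[i] = m / mass_per_ppm
            m *= 1.0 - share  # withdrawal after the measurement
    else:
        clean = c0 * np.exp(-k * times)

    noisy = clean * (1.0 + rng.normal(0.0, noise_sd, size=times.shape)) if noise_sd > 0 else clean
    if np.any(noisy <= 0):
        raise ValidationError("noise drove a mixing ratio non-positive; lower noise_sd")
    series = GasTimeSeries(
        times=times,
        mixing_ratios=noisy,
        bottle=bottle,
        gas_sample_volume=gas_sample_volume,
        liquid_sample_volume=liquid_sample_volume,
    )
    truth = {"k": k, "c0": c0, "noise_sd": noise_sd, "clean_ppm": clean,
             "sampling_losses": sampling_losses}
    return series, truth


def gen_gas_batch(
    ks,
    c0: float,
    times,
    noise_sd: float,
    bottle: BottleSpec | None = None,
    seed: int | None = None,
) -> list[tuple[GasTimeSeries, dict]]:
    """Batch of independent noisy decay series, one per rate constant."""
    rng = np.random.default_rng(seed)
    out = []
    for k in ks:
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(gen_gas_series(k, c0, times, noise_sd, bottle, seed=sub))
    return out


def gen_community(
    n_per_group: int = 8,
    n_otus: int = 50,
    base_concentration=3.0,
    indicators: list[tuple[int, str, float, float]] | None = None,
    depth: int = 10_000,
    seed: int | None = None,
    group_names: tuple[str, str] = ("0.1%", "1%"),
) -> tuple[OTUTable, dict]:
    """Two-group Dirichlet-multinomial OTU table with planted indicators.

    indicators: list of (otu_index, group_name, fold_effect, occupancy).
    A planted indicator's Dirichlet parameter is multiplied by fold_effect
    in its target group, and within that group the OTU is present in each
    sample with probability `occupancy`. Counts per sample are multinomial
    at the given depth, so per-sample totals equal `depth` exactly.
    """
    if depth <= 0:
        raise ValidationError("sequencing depth must be positive")
    if n_per_group < 2:
        raise ValidationError("need at least two samples per group")
    indicators = indicators or []
    for otu, group, fold, occ in indicators:
        if fold <= 0:
            raise ValidationError("fold_effect must be positive")
        if not 0 <= occ <= 1:
            raise ValidationError("occupancy must lie in [0, 1]")
        if group not in group_names:
            raise ValidationError(f"unknown indicator group {group!r}")
        if not 0 <= otu < n_otus:
            raise ValidationError("indicator OTU index out of range")

    base = np.broadcast_to(np.asarray(base_concentration, dtype=float), (n_otus,)).copy()
    if np.any(base <= 0):
        raise ValidationError("Dirichlet parameters must be positive")
    rng = np.random.default_rng(seed)

    alphas = {}
    for g in group_names:
        alpha = base.copy()
        for otu, group, fold, _ in indicators:
            if group == g:
                alpha[otu] *= fold
        alphas[g] = alpha

    rows, labels, sample_ids = [], [], []
    for g in group_names:
        for s in range(n_per_group):
            p = rng.dirichlet(alphas[g])
            for otu, group, _, occ in indicators:
                if group == g and occ < 1.0 and rng.random() > occ:
                    p[otu] = 0.0
            total = p.sum()
            if total == 0:
                raise ValidationError("degenerate sample with zero total proportion")
            rows.append(rng.multinomial(depth, p / total))
            labels.append(g)
            sample_ids.append(f"{g}_s{s}")

    counts = pd.DataFrame(
        np.array(rows), index=sample_ids, columns=[f"OTU_{i}" for i in range(n_otus)]
    )
    metadata = pd.DataFrame(
        {
            "ch4_level": labels,
            "temperature": [8 if i % 2 == 0 else 15 for i in range(len(labels))],
            "block": [f"B{i % 2 + 1}" for i in range(len(labels))],
        },
        index=counts.index,
    )
    table = OTUTable(counts=counts, sample_metadata=metadata)
    truth = {
        "indicators": [
            {"otu": f"OTU_{o}", "group": g, "fold_effect": f, "occupancy": occ}
            for o, g, f, occ in indicators
        ],
        "group_labels": labels,
        "depth": depth,
    }
    return table, truth


def gen_reference_orfs(
    n: int = 5, length: int = 465, seed: int | None = None,
    taxonomy_prefix: str = "Methylococcaceae;Methylobacter",
) -> list[tuple[str, str]]:
    """Synthetic pmoA-like open reading frames: stop-free in frame 0,
    length a multiple of three inside the mb661R window by default."""
    if length % 3 != 0:
        raise ValidationError("ORF length must be a multiple of three")
    rng = np.random.default_rng(seed)
    refs = []
    for i in range(n):
        codons = rng.choice(_NONSTOP_CODONS, size=length // 3)
        refs.append((f"{taxonomy_prefix};ref_{i}", "".join(codons)))
    return refs


def gen_amplicons(
    references: list[tuple[str, str]] | list[str],
    n_reads: int,
    defect_rates: dict | None = None,
    seed: int | None = None,
    quality_high: int = 36,
    quality_low: int = 14,
    window: int = 50,
) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Reads copied from reference ORFs with planted, mutually exclusive defects.

    defect_rates keys: stop_codon (an in-frame stop substituted), frameshift
    (one nucleotide deleted, breaking the codon phase), low_quality_window
    (one 50-nt stretch dropped to quality_low). Remaining reads are clean.
    The truth table labels every read so the filters' pass/fail partition
    can be checked exactly.
    """
    if not references:
        raise ValidationError("reference set is empty")
    rates = dict(defect_rates or {})
    classes = ["stop_codon", "frameshift", "low_quality_window"]
    probs = np.array([rates.get(c, 0.0) for c in classes])
    if np.any(probs < 0) or probs.sum() > 1:
        raise ValidationError("defect rates must lie in [0,1] and sum to <= 1")
    seqs = [r[1] if isinstance(r, tuple) else r for r in references]
    rng = np.random.default_rng(seed)

    reads, truth = [], []
    for i in range(n_reads):
        ref = seqs[int(rng.integers(len(seqs)))]
        u = rng.random()
        cum = np.cumsum(probs)
        defect = "clean"
        for c, edge in zip(classes, cum):
            if u < edge:
                defect = c
                break
        seq = ref
        quals = rng.integers(quality_high - 4, quality_high + 4, size=len(ref)).astype(float)
        if defect == "stop_codon":
            codon_idx = int(rng.integers(1, len(ref) // 3))
            stop = str(rng.choice(sorted(STOP_CODONS)))
            seq = ref[: codon_idx * 3] + stop + ref[codon_idx * 3 + 3 :]
        elif defect == "frameshift":
            pos = int(rng.integers(len(ref)))
            seq = ref[:pos] + ref[pos + 1 :]
            quals = quals[:-1]
        elif defect == "low_quality_window":
            start = int(rng.integers(0, len(ref) - window + 1))
            quals[start : start + window] = quality_low
        reads.append(AmpliconRead(id=f"read_{i}", nucleotides=seq, qualities=quals))
        truth.append({"read_id": f"read_{i}", "defect": defect})
    return reads, pd.DataFrame(truth).set_index("read_id")


def gen_dilution_cq(
    slope: float = -3.3219,
    intercept: float = 38.0,
    levels=None,
    replicates: int = 3,
    noise_sd_cq: float = 0.0,
    seed: int | None = None,
) -> DilutionStandard:
    """Log-linear dilution series Cq = intercept + slope log10(copies) + noise.

    Default levels span the seven-decade range 7.15e6 down to 7.15 copies
    per reaction.
    """
    levels = DEFAULT_STANDARD_LEVELS if levels is None else np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    copies = np.repeat(levels, replicates)
    cq = intercept + slope * np.log10(copies)
    if noise_sd_cq > 0:
        cq = cq + rng.normal(0.0, noise_sd_cq, size=cq.shape)
    return DilutionStandard(copies=copies, cq=cq)


def random_tree(
    n_taxa: int, seed: int | None = None, branch_range: tuple[float, float] = (0.05, 0.2)
) -> TreeNode:
    """Random binary tree with uniform branch lengths, leaves t0..t{n-1}."""
    if n_taxa < 2:
        raise ValidationError("need at least two taxa")
    rng = np.random.default_rng(seed)
    lo, hi = branch_range
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.uniform(lo, hi))
        right.length = float(rng.uniform(lo, hi))
        nodes.append(TreeNode(children=[left, right]))
    return nodes[0]


def evolve_sequences(
    tree: TreeNode, length: int, seed: int | None = None
) -> tuple[Alignment, TreeNode]:
    """Evolve sequences along a tree under the Jukes-Cantor model.

    The root sequence is uniform over ACGT; along each branch of length d
    (substitutions/site) every site differs from its ancestor with the JC
    transition probability p = (3/4)(1 - exp(-4d/3)), mutating uniformly
    to one of the other three bases. Returns the leaf alignment and the
    generating tree (the truth record).
    """
    if length <= 0:
        raise ValidationError("alignment length must be positive")
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=length)
    ids, rows = [], []
    for node in tree.preorder(include_self=True):
        if node.is_root():
            seqs[id(node)] = root_seq
        else:
            parent_seq = seqs[id(node.parent)]
            d = node.length or 0.0
            p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            mutate = rng.random(length) < p
            seq = parent_seq.copy()
            if mutate.any():
                shifts = rng.integers(1, 4, size=int(mutate.sum()))
                seq[mutate] = (seq[mutate] + shifts) % 4
            seqs[id(node)] = seq
        if node.is_tip():
            ids.append(node.name)
            rows.append("".join(_BASES[seqs[id(node)]]))
    return Alignment.from_sequences(ids, rows), tree
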