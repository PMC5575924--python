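"""Seeded generator of synthetic array and cas tables.

The generator emulates the statistical structure the analyses assume, not
sequences: spacer counts are geometric (failures form, truncated below at
``min_spacers``), array start positions follow either a uniform or a
clustered circular model, replicons carry a configurable number of arrays
and operons (default: 82% of genomes have exactly one operon), and an
optional *proximal bias* shrinks the expected size of the cas-adjacent
array as the number of arrays on the replicon grows — the mechanism that
produces a negative multiplicity-size association downstream.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``, so a fixed config yields byte-identical tables.

Truncation uses the memorylessness of the geometric distribution:
``X | X >= m`` has the same law as ``m + X``, so truncated draws are exact
and vectorizable rather than redrawn in a loop.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .records import ArrayRecord, CasOperon

# physical size of an array with k spacers: leading repeat + k (spacer+repeat)
_REPEAT_BP = 36
_SPACER_BP = 30
_PLACEMENT_RETRIES = 200

# subtype mix loosely proportional to the relative abundance of the
# well-represented Class 1 groups (I-B, I-C, I-E, I-F and Type III)
_DEFAULT_SUBTYPE_WEIGHTS = {
    "I-B": 0.24,
    "I-C": 0.21,
    "I-E": 0.29,
    "I-F": 0.13,
    "III": 0.13,
}


class PlacementError(RuntimeError):
    """Feature placement failed (replicon too crowded); names the replicon."""


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic genome-table generator.

    Defaults describe the study conditions: 811 genomes, geometric spacer
    counts with p = 0.025 (mean ~ 39), mostly single-operon replicons
    (mass 0.82 on one operon), uniform positions, and no proximal bias
    unless requested.
    """

    n_genomes: int = 811
    replicon_length_range: Tuple[int, int] = (1_500_000, 6_000_000)
    p_geometric: float = 0.025
    min_spacers: int = 1
    n_arrays_weights: Dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.25, 3: 0.12, 4: 0.08, 5: 0.05}
    )
    n_operons_weights: Dict[int, float] = field(
        default_factory=lambda: {1: 0.82, 2: 0.18}
    )
    position_model: str = "uniform"  # or "clustered"
    cluster_center_deg: float = 220.0
    cluster_mass: float = 0.5
    cluster_width_deg: float = 60.0
    minus_strand_prob: float = 0.5
    proximal_bias: float = 0.0
    questionable_prob: float = 0.05
    plasmid_prob: float = 0.05
    type_subtype_weights: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUBTYPE_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.replicon_length_range
        if not lo < hi:
            raise ValueError("replicon_length_range must satisfy min < max")
        if not (0.0 < self.p_geometric < 1.0):
            raise ValueError("p_geometric must be in (0, 1)")
        if self.min_spacers < 0:
            raise ValueError("min_spacers must be >= 0 (0 = untruncated mode)")
        for name in ("cluster_mass", "minus_strand_prob", "questionable_prob", "plasmid_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.proximal_bias < 0:
            raise ValueError("proximal_bias must be >= 0")
        if self.position_model not in ("uniform", "clustered"):
            raise ValueError("position_model must be 'uniform' or 'clustered'")
        for name in ("n_arrays_weights", "n_operons_weights", "type_subtype_weights"):
            w = getattr(self, name)
            total = sum(w.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in w.values()):
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_arrays_weights", "n_operons_weights"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        if "replicon_length_range" in raw:
            raw["replicon_length_range"] = tuple(raw["replicon_length_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["replicon_length_range"] = list(d["replicon_length_range"])
        return d


def truncated_geometric(
    rng: np.random.Generator, p: float, size: int, min_value: int
) -> np.ndarray:
    """Failures-geometric draws conditioned on >= min_value (exact, via
    memorylessness)."""
    base = rng.geometric(p, size) - 1  # failures form on {0, 1, ...}
    return base + min_value


def truncated_geometric_mean(p: float, min_value: int) -> float:
    """E[X | X >= min_value] for the failures-geometric."""
    return min_value + (1.0 - p) / p


def proximal_shrinkage(bias: float, n_arrays: int) -> float:
    """Multiplicative shrinkage of the proximal array's mean size."""
    return (1.0 + bias) ** (n_arrays - 1)


def biased_geometric_p(p: float, bias: float, n_arrays: int) -> float:
    """Geometric parameter whose mean is the base mean shrunk by the bias."""
    mean = (1.0 - p) / p / proximal_shrinkage(bias, n_arrays)
    return 1.0 / (1.0 + mean)


def simulate_positions(
    n: int,
    position_model: str = "uniform",
    cluster_center_deg: float = 220.0,
    cluster_mass: float = 0.5,
    cluster_width_deg: float = 60.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw n angular positions in degrees on [0, 360).

    The clustered model places ``cluster_mass`` of the points uniformly
    within ``cluster_width_deg`` of the center (wrapping across 0/360) and
    the remainder uniformly on the whole circle.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if position_model == "uniform":
        return rng.uniform(0.0, 360.0, n)
    if position_model != "clustered":
        raise ValueError("position_model must be 'uniform' or 'clustered'")
    in_cluster = rng.random(n) < cluster_mass
    out = rng.uniform(0.0, 360.0, n)
    half = cluster_width_deg / 2.0
    clustered = (cluster_center_deg + rng.uniform(-half, half, n)) % 360.0
    return np.where(in_cluster, clustered, out)


def inject_proximal_bias(
    sizes: np.ndarray,
    is_proximal: np.ndarray,
    n_arrays: np.ndarray,
    p_geometric: float,
    proximal_bias: float,
    seed: int = 0,
    min_spacers: int = 1,
) -> np.ndarray:
    """Redraw proximal-array sizes from the shrunk-mean geometric.

    With ``proximal_bias = 0`` the input is returned unchanged (identity).
    For a proximal array on a replicon with m arrays, the new size is a
    truncated geometric draw whose untruncated mean is the base mean
    divided by ``(1 + bias)**(m - 1)``.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if proximal_bias == 0:
        return sizes.copy()
    is_proximal = np.asarray(is_proximal, dtype=bool)
    n_arrays = np.asarray(n_arrays, dtype=np.int64)
    rng = np.random.default_rng(seed)
    out = sizes.copy()
    for i in np.flatnonzero(is_proximal):
        p_eff = biased_geometric_p(p_geometric, proximal_bias, int(n_arrays[i]))
        out[i] = truncated_geometric(rng, p_eff, 1, min_spacers)[0]
    return out


def _array_span(n_spacers: int) -> int:
    return _REPEAT_BP + n_spacers * (_SPACER_BP + _REPEAT_BP)


def _deg_to_start(deg: float, length: int) -> int:
    start = int(round(deg / 360.0 * length))
    return min(max(start, 1), length)


def _overlaps(start: int, end: int, occupied: List[Tuple[int, int]]) -> bool:
    return any(not (end < s or e < start) for s, e in occupied)


def _place(
    rng: np.random.Generator,
    span: int,
    length: int,
    occupied: List[Tuple[int, int]],
    accession: str,
    cfg: SimulationConfig,
    fixed_start: Optional[int] = None,
) -> Tuple[int, int]:
    """Find a non-overlapping [start, end] for a feature of the given span."""
    if fixed_start is not None:
        start = min(max(fixed_start, 1), max(length - span + 1, 1))
        end = start + span - 1
        if end <= length and not _overlaps(start, end, occupied):
            occupied.append((start, end))
            return start, end
        # fall through to random placement if the requested spot is taken
    for _ in range(_PLACEMENT_RETRIES):
        deg = simulate_positions(
            1,
            cfg.position_model,
            cfg.cluster_center_deg,
            cfg.cluster_mass,
            cfg.cluster_width_deg,
            rng=rng,
        )[0]
        start = _deg_to_start(deg, length)
        if start + span - 1 > length:
            continue
        end = start + span - 1
        if not _overlaps(start, end, occupied):
            occupied.append((start, end))
            return start, end
    raise PlacementError(
        f"could not place a {span} bp feature on replicon {accession} "
        f"after {_PLACEMENT_RETRIES} attempts"
    )


def _weighted_choice(rng: np.random.Generator, weights: Dict) -> object:
    keys = list(weights.keys())
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _strand(rng: np.random.Generator, minus_prob: float) -> str:
    return "-" if rng.random() < minus_prob else "+"


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[List[ArrayRecord], List[CasOperon]]:
    """Generate matched array and cas tables under the config.

    Deterministic for a fixed config (single seeded generator, sequential
    draws).  Each genome gets one chromosome with its configured number of
    operons and arrays; the first array is placed adjacent to the first
    operon and is the one subject to the proximal size bias.  Optional
    extras exercise the filters: a questionable decoy array and a plasmid
    replicon carrying a cas-less array.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.replicon_length_range
    arrays: List[ArrayRecord] = []
    operons: List[CasOperon] = []

    for i in range(config.n_genomes):
        accession = f"SYN{i:05d}.1"
        organism = f"Synthetic organism {i:05d}"
        length = int(rng.integers(lo, hi + 1))
        n_ops = int(_weighted_choice(rng, config.n_operons_weights))
        n_arr = int(_weighted_choice(rng, config.n_arrays_weights))

        # sizes: array 0 is cas-proximal by construction and feels the bias
        sizes = truncated_geometric(
            rng, config.p_geometric, n_arr, config.min_spacers
        )
        if config.proximal_bias > 0 and n_arr > 1:
            p_eff = biased_geometric_p(
                config.p_geometric, config.proximal_bias, n_arr
            )
            sizes[0] = truncated_geometric(rng, p_eff, 1, config.min_spacers)[0]

        occupied: List[Tuple[int, int]] = []
        op_len = int(rng.integers(5_000, 15_001))
        arr0_span = _array_span(int(sizes[0]))

        # place the proximal array per the position model, operon adjacent
        deg0 = simulate_positions(
            1,
            config.position_model,
            config.cluster_center_deg,
            config.cluster_mass,
            config.cluster_width_deg,
            rng=rng,
        )[0]
        arr0_start, arr0_end = _place(
            rng, arr0_span, length, occupied, accession, config,
            fixed_start=_deg_to_start(deg0, length),
        )
        gap = int(rng.integers(50, 2_001))
        op_start_wanted = arr0_start - gap - op_len
        if op_start_wanted < 1:
            op_start_wanted = arr0_end + gap
        op_start, op_end = _place(
            rng, op_len, length, occupied, accession, config,
            fixed_start=op_start_wanted,
        )
        subtype = _weighted_choice(rng, config.type_subtype_weights)
        system_type = "III" if subtype == "III" else "I"
        operons.append(
            CasOperon(
                accession=accession,
                system_class=1,
                system_type=system_type,
                subtype=None if subtype == "III" else subtype,
                operon_start_bp=op_start,
                operon_end_bp=op_end,
                strand=_strand(rng, config.minus_strand_prob),
                has_cas1=True,
            )
        )
        arr_rows = [(arr0_start, arr0_end, int(sizes[0]))]

        for j in range(1, n_arr):
            span = _array_span(int(sizes[j]))
            s, e = _place(rng, span, length, occupied, accession, config)
            arr_rows.append((s, e, int(sizes[j])))

        for k in range(1, n_ops):
            op_len_k = int(rng.integers(5_000, 15_001))
            s, e = _place(rng, op_len_k, length, occupied, accession, config)
            subtype_k = _weighted_choice(rng, config.type_subtype_weights)
            type_k = "III" if subtype_k == "III" else "I"
            operons.append(
                CasOperon(
                    accession=accession,
                    system_class=1,
                    system_type=type_k,
                    subtype=None if subtype_k == "III" else subtype_k,
                    operon_start_bp=s,
                    operon_end_bp=e,
                    strand=_strand(rng, config.minus_strand_prob),
                    has_cas1=True,
                )
            )

        questionable_flags = [False] * n_arr
        if rng.random() < config.questionable_prob:
            size_q = int(
                truncated_geometric(rng, config.p_geometric, 1, config.min_spacers)[0]
            )
            s, e = _place(rng, _array_span(size_q), length, occupied, accession, config)
            arr_rows.append((s, e, size_q))
            questionable_flags.append(True)

        for j, (s, e, size) in enumerate(arr_rows, start=1):
            arrays.append(
                ArrayRecord(
                    accession=accession,
                    organism=organism,
                    replicon_kind="chromosome",
                    replicon_length=length,
                    array_id=f"arr{j}",
                    start_bp=s,
                    end_bp=e,
                    n_spacers=size,
                    strand=_strand(rng, config.minus_strand_prob),
                    questionable=questionable_flags[j - 1],
                )
            )

        if rng.random() < config.plasmid_prob:
            p_len = int(rng.integers(20_000, 300_001))
            p_acc = f"SYN{i:05d}.2"
            size_p = int(
                truncated_geometric(rng, config.p_geometric, 1, config.min_spacers)[0]
            )
            span = _array_span(size_p)
            start = int(rng.integers(1, max(p_len - span, 2)))
            arrays.append(
                ArrayRecord(
                    accession=p_acc,
                    organism=organism,
                    replicon_kind="plasmid",
                    replicon_length=p_len,
                    array_id="arr1",
                    start_bp=start,
                    end_bp=start + span - 1,
                    n_spacers=size_p,
                    strand=_strand(rng, config.minus_strand_prob),
                    questionable=False,
                )
            )

    return arrays, operons
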