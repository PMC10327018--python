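"""Readers/writers for the tabular and skeleton formats the pipeline touches.

Three on-disk formats are supported: delimited annotation tables (one row per
neuron, hierarchical flow -> superclass -> class -> cell type labels), SWC
skeletons, and CSV synaptic edge tables resolved by neuropil.  All coordinates
are micrometres; a single unit throughout avoids silent nm/um mix-ups.

Vocabulary checks on annotation tables warn rather than fail: real-world
tables carry evolving labels and rejecting them would make round-tripping
community data impossible.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SIDES",
    "FLOWS",
    "SUPERCLASSES",
    "NeuronRecord",
    "Skeleton",
    "EdgeTable",
    "RunConfig",
    "read_annotation_table",
    "write_annotation_table",
    "read_swc",
    "write_swc",
    "read_edge_table",
    "write_edge_table",
]

SIDES = frozenset({"left", "right", "center", "na"})
FLOWS = frozenset({"afferent", "efferent", "intrinsic"})
#: The nine-value superclass vocabulary for a whole-brain connectome.
SUPERCLASSES = frozenset(
    {
        "sensory",
        "motor",
        "endocrine",
        "ascending",
        "descending",
        "visual_projection",
        "visual_centrifugal",
        "optic",
        "central",
    }
)

_ANNOTATION_COLUMNS = (
    "neuron_id",
    "dataset",
    "side",
    "soma_x",
    "soma_y",
    "soma_z",
    "flow",
    "superclass",
    "class",
    "hemilineage",
    "cell_type",
    "hemibrain_type",
)


@dataclass
class NeuronRecord:
    """One neuron's identity plus its hierarchical annotations.

    ``cell_type`` takes precedence over ``hemibrain_type`` when both are
    present (refinements such as splits of a reference type are recorded in
    ``cell_type``); :attr:`effective_type` applies that rule.
    """

    neuron_id: str
    dataset: str
    side: str = "na"
    soma_xyz: tuple[float, float, float] | None = None
    flow: str | None = None
    superclass: str | None = None
    class_: str | None = None
    hemilineage: str | None = None
    cell_type: str | None = None
    hemibrain_type: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def effective_type(self) -> str | None:
        return self.cell_type if self.cell_type else self.hemibrain_type

    @property
    def hemisphere(self) -> str:
        """Dataset+side tag, the unit of comparison across brains."""
        return f"{self.dataset}:{self.side}"


def _clean(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    return s or None


def read_annotation_table(path) -> list[NeuronRecord]:
    """Read a CSV/TSV annotation table into :class:`NeuronRecord` objects.

    Unknown columns are preserved in ``record.extra``.  Unknown enum values
    (side/flow/superclass) are reported with their row number but the record
    is kept.  A missing ``neuron_id`` column is fatal.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "neuron_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'neuron_id'")
    known = set(_ANNOTATION_COLUMNS)
    records: list[NeuronRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        side = _clean(row.get("side")) or "na"
        flow = _clean(row.get("flow"))
        superclass = _clean(row.get("superclass"))
        if side not in SIDES:
            warnings.warn(f"row {i}: unknown side {side!r}")
        if flow is not None and flow not in FLOWS:
            warnings.warn(f"row {i}: unknown flow {flow!r}")
        if superclass is not None and superclass not in SUPERCLASSES:
            warnings.warn(f"row {i}: unknown superclass {superclass!r}")
        soma = None
        if all(_clean(row.get(c)) is not None for c in ("soma_x", "soma_y", "soma_z")):
            soma = tuple(float(row[c]) for c in ("soma_x", "soma_y", "soma_z"))
        nid = _clean(row.get("neuron_id"))
        if nid is None:
            raise ValueError(f"{path}: row {i}: empty neuron_id")
        records.append(
            NeuronRecord(
                neuron_id=nid,
                dataset=_clean(row.get("dataset")) or "na",
                side=side,
                soma_xyz=soma,
                flow=flow,
                superclass=superclass,
                class_=_clean(row.get("class")),
                hemilineage=_clean(row.get("hemilineage")),
                cell_type=_clean(row.get("cell_type")),
                hemibrain_type=_clean(row.get("hemibrain_type")),
                extra={k: row[k] for k in row if k not in known},
            )
        )
    ids = [(r.dataset, r.side, r.neuron_id) for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate neuron_id within a hemisphere")
    return records


def write_annotation_table(records: Sequence[NeuronRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "neuron_id": r.neuron_id,
            "dataset": r.dataset,
            "side": r.side,
            "soma_x": r.soma_xyz[0] if r.soma_xyz else None,
            "soma_y": r.soma_xyz[1] if r.soma_xyz else None,
            "soma_z": r.soma_xyz[2] if r.soma_xyz else None,
            "flow": r.flow,
            "superclass": r.superclass,
            "class": r.class_,
            "hemilineage": r.hemilineage,
            "cell_type": r.cell_type,
            "hemibrain_type": r.hemibrain_type,
        }
        row.update(r.extra)
        rows.append(row)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


class Skeleton:
    """A neuron skeleton: a rooted tree of 3-D nodes with radii (micrometres).

    Exactly one root (parent id -1) per skeleton; every parent id must refer
    to an existing node; the parent relation must be acyclic.
    """

    def __init__(self, node_ids, parent_ids, xyz, radius=None, *, validate=True):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if radius is None:
            radius = np.ones(len(self.node_ids))
        self.radius = np.asarray(radius, dtype=float)
        if validate:
            self._validate()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.node_ids)

    def __repr__(self) -> str:
        return f"<Skeleton {len(self)} nodes, root {self.root}>"

    def _validate(self) -> None:
        n = len(self.node_ids)
        if n == 0:
            raise ValueError("empty skeleton")
        if len(set(self.node_ids.tolist())) != n:
            raise ValueError("duplicate node ids")
        roots = self.node_ids[self.parent_ids == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found roots {roots.tolist()}")
        idset = set(self.node_ids.tolist())
        dangling = [p for p in self.parent_ids.tolist() if p != -1 and p not in idset]
        if dangling:
            raise ValueError(f"dangling parent ids {sorted(set(dangling))}")
        # acyclicity: walking rootward from every node must terminate
        parent = dict(zip(self.node_ids.tolist(), self.parent_ids.tolist()))
        for start in self.node_ids.tolist():
            seen = set()
            node = start
            while node != -1:
                if node in seen:
                    raise ValueError("cycle detected in parent relation")
                seen.add(node)
                node = parent[node]

    @property
    def root(self) -> int:
        return int(self.node_ids[self.parent_ids == -1][0])

    def index_of(self, node_id) -> int:
        return int(np.nonzero(self.node_ids == node_id)[0][0])

    def parent_index(self) -> np.ndarray:
        """Positional index of each node's parent (-1 for the root)."""
        pos = {nid: i for i, nid in enumerate(self.node_ids.tolist())}
        return np.array(
            [pos[p] if p != -1 else -1 for p in self.parent_ids.tolist()], dtype=np.int64
        )

    def cable_length(self) -> float:
        """Total cable length: sum of parent-child Euclidean distances (um)."""
        pi = self.parent_index()
        has_parent = pi >= 0
        d = np.linalg.norm(self.xyz[has_parent] - self.xyz[pi[has_parent]], axis=1)
        return float(d.sum())

    def copy(self) -> "Skeleton":
        return Skeleton(
            self.node_ids.copy(), self.parent_ids.copy(), self.xyz.copy(),
            self.radius.copy(), validate=False,
        )


def read_swc(path) -> Skeleton:
    """Read an SWC file (whitespace-delimited, '#' comments, 1-based ids)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (int(parts[0]), float(parts[2]), float(parts[3]), float(parts[4]),
                     float(parts[5]), int(parts[6]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable SWC row") from exc
    if not rows:
        raise ValueError(f"{path}: no SWC nodes")
    arr = np.array(rows, dtype=float)
    try:
        return Skeleton(
            node_ids=arr[:, 0].astype(np.int64),
            parent_ids=arr[:, 5].astype(np.int64),
            xyz=arr[:, 1:4],
            radius=arr[:, 4],
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_swc(skel: Skeleton, path) -> None:
    """Write a skeleton as SWC (structure type column written as 0)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid, (x, y, z), r, pid in zip(
            skel.node_ids.tolist(), skel.xyz, skel.radius.tolist(), skel.parent_ids.tolist()
        ):
            fh.write(f"{nid} 0 {x:.6f} {y:.6f} {z:.6f} {r:.6f} {pid}\n")


EDGE_COLUMNS = ("pre_id", "post_id", "neuropil", "weight")


class EdgeTable:
    """Directed synaptic connections with integer counts, neuropil-resolved.

    Stored as a DataFrame with columns ``pre_id, post_id, neuropil, weight``;
    (pre, post, neuropil) is unique and every stored weight is >= 1.
    """

    def __init__(self, df: pd.DataFrame, *, validate=True, _sum_duplicates=True):
        df = pd.DataFrame(df, columns=list(EDGE_COLUMNS)).copy()
        df["weight"] = pd.to_numeric(df["weight"])
        if validate:
            frac = df["weight"] % 1 != 0
            if frac.any():
                raise ValueError(
                    f"non-integer weight at rows {df.index[frac].tolist()[:5]}"
                )
            neg = df["weight"] < 1
            if neg.any():
                raise ValueError(
                    f"weight < 1 at rows {df.index[neg].tolist()[:5]}"
                )
        df["weight"] = df["weight"].astype(np.int64)
        if _sum_duplicates and df.duplicated(["pre_id", "post_id", "neuropil"]).any():
            warnings.warn("duplicate (pre, post, neuropil) rows summed")
            df = (
                df.groupby(["pre_id", "post_id", "neuropil"], as_index=False, sort=False)
                .agg(weight=("weight", "sum"))
            )
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "EdgeTable":
        return cls(pd.DataFrame(rows, columns=list(EDGE_COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def total_weight(self) -> int:
        return int(self.df["weight"].sum())

    def aggregate_neuropils(self) -> pd.DataFrame:
        """Sum weights over neuropils -> neuron-pair weights."""
        return (
            self.df.groupby(["pre_id", "post_id"], as_index=False)
            .agg(weight=("weight", "sum"))
        )

    def sorted(self) -> pd.DataFrame:
        return self.df.sort_values(list(EDGE_COLUMNS[:3])).reset_index(drop=True)

    def equals(self, other: "EdgeTable") -> bool:
        return self.sorted().equals(other.sorted())


def read_edge_table(path) -> EdgeTable:
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str, "neuropil": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    try:
        return EdgeTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_edge_table(table: EdgeTable, path) -> None:
    table.df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """All stage parameters with their defaults; YAML round-trip identical.

    Rates are fractions in (0, 1]; lengths in micrometres; weights in
    synapses.  ``seed`` feeds every stochastic stage.
    """

    seed: int = 0
    # morphology
    prune_twigs_um: float = 5.0
    resample_spacing_um: float = 1.0
    dotprops_k: int = 5
    nblast_sigma_um: float = 3.0
    midline_x_um: float = 0.0
    # candidate matching / consensus
    candidate_percentile: float = 90.0
    balance_tolerance: float = 3.0
    min_per_hemisphere: int = 1
    # synthetic generator
    median_weight: float = 4.0
    sigma_log10: float = 0.6
    weight_cv: float = 0.3
    morph_jitter_sd_um: float = 0.5
    count_jitter_p: float = 0.2
    dropout_scale: float = 5.0
    # technical noise
    precision: float = 0.72
    recall: float = 0.77
    noise_rounds: int = 500
    noise_weight_range: tuple[int, int] = (1, 30)
    band_quantiles: tuple[float, float] = (0.05, 0.95)

    def to_yaml(self, path=None) -> str:
        data = asdict(self)
        data["noise_weight_range"] = list(self.noise_weight_range)
        data["band_quantiles"] = list(self.band_quantiles)
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        data["noise_weight_range"] = tuple(data["noise_weight_range"])
        data["band_quantiles"] = tuple(data["band_quantiles"])
        return cls(**data)
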