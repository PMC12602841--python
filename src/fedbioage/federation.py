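"""Simulated client/server federated averaging.

The server is in-process and clients run sequentially: each round every client
trains locally for a fixed number of epochs starting from the shared parameter
vector, the server aggregates the returned vectors (sample-size-weighted or
equal), and the cycle repeats until a round cap or until the size-weighted
validation MAE stops changing. The protocol is model-agnostic: any object
satisfying :class:`ModelAdapter` can be federated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ParamVector:
    """Flat parameter vector with a named-segment layout.

    ``layout`` maps group names to (start, stop) index pairs that partition
    the vector exactly; it travels with the values so clients and server can
    verify they are exchanging compatible models.
    """

    values: np.ndarray
    layout: dict[str, tuple[int, int]]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("ParamVector entries must be finite")
        spans = sorted(self.layout.values())
        pos = 0
        for start, stop in spans:
            if start != pos or stop < start:
                raise ValueError(f"layout segments must partition [0, {v.size}); got {self.layout}")
            pos = stop
        if pos != v.size:
            raise ValueError("layout does not cover the whole vector")

    def get(self, name: str) -> np.ndarray:
        start, stop = self.layout[name]
        return self.values[start:stop]

    def with_values(self, values: np.ndarray) -> "ParamVector":
        return ParamVector(np.asarray(values, dtype=float), self.layout)

    def same_layout(self, other: "ParamVector") -> bool:
        return self.layout == other.layout

    def checksum(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.values).tobytes()).hexdigest()[:16]


class ModelAdapter(Protocol):
    """What the engine needs from a model: loss, local training, validation MAE."""

    def init_params(self, seed: int) -> ParamVector: ...

    def loss(self, params: ParamVector, data: pd.DataFrame) -> float: ...

    def train(
        self, params: ParamVector, data: pd.DataFrame, epochs: int, batch_size: int | None, seed: int
    ) -> tuple[ParamVector, float]: ...

    def val_mae(self, params: ParamVector, data: pd.DataFrame) -> float: ...


@dataclass(frozen=True)
class FederationConfig:
    rounds: int = 20
    local_epochs: int = 3
    batch_size: int | None = 8
    aggregation: str = "n_weighted"  # or "equal"
    convergence_tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.rounds < 1 or self.local_epochs < 0:
            raise ValueError("rounds must be >= 1 and local_epochs >= 0")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 (or None for full batch)")
        if self.aggregation not in ("n_weighted", "equal"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")


@dataclass
class RoundLog:
    """Per-round, per-cohort training loss and validation MAE plus a checksum."""

    records: list[dict] = field(default_factory=list)

    def append(self, round_idx: int, cohort: str, train_loss: float, val_mae: float, checksum: str):
        self.records.append(
            {
                "round": round_idx,
                "cohort": cohort,
                "train_loss": train_loss,
                "val_mae": val_mae,
                "params_checksum": checksum,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def n_rounds(self) -> int:
        return 0 if not self.records else max(r["round"] for r in self.records)


def client_seed(master_seed: int, cohort: str, round_idx: int) -> int:
    """Stable per-(cohort, round) stream seed; independent of client ordering."""
    digest = hashlib.sha256(f"{master_seed}|{cohort}|{round_idx}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def local_update(
    params: ParamVector,
    adapter: ModelAdapter,
    data: pd.DataFrame,
    epochs: int,
    batch_size: int | None,
    seed: int = 0,
) -> tuple[ParamVector, float]:
    """One client's local training pass starting from the shared parameters.

    ``epochs = 0`` returns the input untouched (loss evaluated, no step).
    The input vector is never modified in place.
    """
    if len(data) == 0:
        raise ValueError("local_update: empty client data")
    if epochs == 0:
        return params.with_values(params.values.copy()), adapter.loss(params, data)
    return adapter.train(params, data, epochs, batch_size, seed)


def aggregate(
    params_list: list[ParamVector], sizes: list[int] | None = None, scheme: str = "n_weighted"
) -> ParamVector:
    """Server-side averaging of client parameter vectors.

    ``n_weighted`` implements the sample-size-weighted mean
    sum_j n_j beta_j / sum_j n_j; ``equal`` the unweighted mean.
    """
    if not params_list:
        raise ValueError("aggregate: empty parameter list")
    ref = params_list[0]
    for p in params_list[1:]:
        if not p.same_layout(ref):
            raise ValueError("aggregate: parameter layouts differ between clients")
    if scheme == "equal":
        weights = np.ones(len(params_list))
    elif scheme == "n_weighted":
        if sizes is None or len(sizes) != len(params_list):
            raise ValueError("n_weighted aggregation requires one size per client")
        if any(s <= 0 for s in sizes):
            raise ValueError("client sizes must be positive")
        weights = np.asarray(sizes, dtype=float)
    else:
        raise ValueError(f"unknown aggregation scheme {scheme!r}")
    weights = weights / weights.sum()
    stacked = np.stack([p.values for p in params_list])
    return ref.with_values(weights @ stacked)


def run_federated(
    clients: list[tuple[str, pd.DataFrame, pd.DataFrame]],
    model_factory,
    config: FederationConfig,
) -> tuple[ParamVector, RoundLog]:
    """Run the full round protocol.

    ``clients`` is a list of (cohort name, training table, validation table).
    Stops at ``config.rounds`` or as soon as the size-weighted mean validation
    MAE changes by less than ``config.convergence_tol`` between rounds. Raises
    on non-finite loss, naming the offending round and cohort.
    """
    config.validate()
    if not clients:
        raise ValueError("run_federated: no clients")
    adapter: ModelAdapter = model_factory()
    global_params = adapter.init_params(config.seed)
    log = RoundLog()
    sizes = [len(train) for _, train, _ in clients]
    prev_mae = None

    for rnd in range(1, config.rounds + 1):
        locals_, losses = [], []
        for name, train, _val in clients:
            upd, loss = local_update(
                global_params,
                adapter,
                train,
                config.local_epochs,
                config.batch_size,
                seed=client_seed(config.seed, name, rnd),
            )
            if not np.isfinite(loss) or not np.all(np.isfinite(upd.values)):
                raise FloatingPointError(f"divergence at round {rnd}, cohort {name!r}")
            locals_.append(upd)
            losses.append(loss)
        global_params = aggregate(locals_, sizes, config.aggregation)

        val_sizes = np.array([len(v) for _, _, v in clients], dtype=float)
        maes = np.array(
            [adapter.val_mae(global_params, val) for _, _, val in clients], dtype=float
        )
        for (name, _, _), loss, mae in zip(clients, losses, maes):
            log.append(rnd, name, loss, mae, global_params.checksum())
        weighted_mae = float(np.average(maes, weights=val_sizes))
        if prev_mae is not None and abs(weighted_mae - prev_mae) < config.convergence_tol:
            break
        prev_mae = weighted_mae
    return global_params, log


def select_best_round(log: RoundLog, rule: str = "global_val_mae", sizes: dict[str, int] | None = None):
    """Pick the checkpoint round from the validation trajectory.

    ``global_val_mae`` returns the round minimizing the (size-weighted, if
    sizes are given) mean validation MAE; ``per_cohort_min`` returns a dict
    mapping each cohort to the round where its own validation MAE is lowest.
    """
    df = log.to_frame()
    if df.empty:
        raise ValueError("select_best_round: empty log")
    if rule == "per_cohort_min":
        return {
            cohort: int(sub.loc[sub["val_mae"].idxmin(), "round"])
            for cohort, sub in df.groupby("cohort")
        }
    if rule == "global_val_mae":
        if sizes:
            df = df.assign(w=df["cohort"].map(sizes))
            agg = df.groupby("round").apply(
                lambda g: np.average(g["val_mae"], weights=g["w"]), include_groups=False
            )
        else:
            agg = df.groupby("round")["val_mae"].mean()
        return int(agg.idxmin())
    raise ValueError(f"unknown rule {rule!r}")


def write_checkpoint(params: ParamVector, stem) -> None:
    """Persist a parameter vector as <stem>.npy with a JSON layout sidecar."""
    import json
    from pathlib import Path

    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), params.values)
    sidecar = {name: list(span) for name, span in params.layout.items()}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_checkpoint(stem) -> ParamVector:
    import json
    from pathlib import Path

    stem = Path(stem)
    values = np.load(stem.with_suffix(".npy"))
    layout = {k: tuple(v) for k, v in json.loads(stem.with_suffix(".json").read_text()).items()}
    return ParamVector(values, layout)
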