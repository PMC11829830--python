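"""Descriptor-based neural regressor with energy/force/feature contract.

The model maps inverse pairwise distances (a rotation/translation invariant
descriptor with a fixed pair ordering taken from the dataset composition)
through a small feed-forward network to the molecular energy. Forces are
obtained by differentiating the predicted energy through the descriptor
(chain rule), never by a separate force head, so they are exactly the
negative gradient of the predicted energy. The last hidden layer is exposed
as the molecule feature vector consumed by the feature-space GMM.

Optional evidential heads ("nig" for DER-S/DER-L, "niw" for DER-M) share
the backbone and add their distribution parameters as extra linear outputs;
an atomic-charge head provides total charge and a point-charge dipole when
charge/dipole labels are present.

Training follows the reference hyperparameters: ADAM, batch size 32,
learning rate 0.001 with a staircase decay, validation every 5 epochs,
early stopping on the validation loss, and an exponential moving average
of the parameters (on by default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import evidential as ev
from .autodiff import Tensor, value_of
from .chemio import Dataset, Structure
from .toysystem import EA_TO_DEBYE

logger = logging.getLogger("pesuq")


@dataclasses.dataclass
class DescriptorConfig:
    """Inverse-distance descriptor, optionally Gaussian-expanded per pair."""

    n_gaussians: int | None = None
    gaussian_range: tuple = (0.2, 1.2)  # on inverse distances, 1/Å
    gaussian_width: float | None = None


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 0.1
    lr_decay_steps: int = 50_000
    max_epochs: int = 300
    validation_every: int = 5  # epochs
    early_stopping_patience: int = 12  # validations without improvement
    hidden: tuple = (128, 128)
    w_e: float = 1.0
    w_f: float = 52.9177
    w_q: float = 14.3996
    w_d: float = 27.2113
    ema: bool = True
    ema_decay: float = 0.999
    loss_variant: str = "ders"  # for the nig head: "ders" or "derl"
    nig_loss: ev.NIGLossConfig = dataclasses.field(
        default_factory=ev.NIGLossConfig
    )
    descriptor: DescriptorConfig = dataclasses.field(
        default_factory=DescriptorConfig
    )

    def __post_init__(self):
        if min(self.w_e, self.w_f, self.w_q, self.w_d) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclasses.dataclass
class PredictionRecord:
    energy: float
    forces: np.ndarray
    features: np.ndarray
    head_outputs: object = None  # None | NIGParams | NIWOutput
    charge: float | None = None
    dipole: np.ndarray | None = None


@dataclasses.dataclass
class EnsemblePrediction:
    member_energies: np.ndarray
    mean: float
    std: float


def ensemble_statistics(member_energies) -> EnsemblePrediction:
    """Committee mean and spread: σ_E = sqrt(1/N Σ (Ẽ_n − Ē)²).

    The population (1/N) normalization is used, so two members predicting
    0 and 2 give σ_E = 1.
    """
    e = np.asarray(member_energies, dtype=float)
    if e.size < 2:
        raise ValueError("a committee needs at least 2 members")
    mean = float(e.mean())
    return EnsemblePrediction(
        member_energies=e,
        mean=mean,
        std=float(np.sqrt(np.mean((e - mean) ** 2))),
    )


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def pair_table(n_atoms: int) -> np.ndarray:
    """Lexicographic (i < j) atom-pair ordering; length n(n-1)/2."""
    return np.array(
        [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)],
        dtype=int,
    )


def _inverse_distances(coords: np.ndarray, pairs: np.ndarray):
    """Inverse distances u_p = 1/r_p and their Jacobian du/dx (flat coords)."""
    rij = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.sqrt(np.sum(rij * rij, axis=1))
    if np.any(r < 0.1):
        raise ValueError("coincident atoms: descriptor singularity")
    u = 1.0 / r
    # du/dx_i = -(1/r^3) (x_i - x_j); du/dx_j = +...
    grad_pair = -(u**3)[:, None] * rij  # (P, 3) w.r.t. atom i
    jac = np.zeros((len(pairs), coords.size))
    for p, (i, j) in enumerate(pairs):
        jac[p, 3 * i : 3 * i + 3] = grad_pair[p]
        jac[p, 3 * j : 3 * j + 3] = -grad_pair[p]
    return u, jac


def featurize(structure_or_coords, config: DescriptorConfig | None = None,
              pairs: np.ndarray | None = None, with_jacobian: bool = False):
    """Descriptor vector for one structure (optionally with its Jacobian).

    Base features are the inverse pairwise distances in the fixed pair
    order; with ``config.n_gaussians`` set, each inverse distance is
    expanded on a Gaussian grid. The descriptor is exactly invariant to
    rigid translations and rotations.
    """
    config = config or DescriptorConfig()
    coords = (
        structure_or_coords.coordinates
        if isinstance(structure_or_coords, Structure)
        else np.asarray(structure_or_coords, dtype=float)
    )
    if pairs is None:
        pairs = pair_table(len(coords))
    u, jac = _inverse_distances(coords, pairs)
    if config.n_gaussians is None:
        return (u, jac) if with_jacobian else u
    lo, hi = config.gaussian_range
    centers = np.linspace(lo, hi, config.n_gaussians)
    width = config.gaussian_width or (hi - lo) / config.n_gaussians
    diff = u[:, None] - centers[None, :]
    phi = np.exp(-(diff**2) / (2 * width**2))  # (P, G)
    feat = phi.ravel()
    if not with_jacobian:
        return feat
    dphi_du = -diff / width**2 * phi
    jac_exp = (dphi_du[:, :, None] * jac[:, None, :]).reshape(
        feat.size, coords.size
    )
    return feat, jac_exp


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

HEAD_DIMS = {"scalar": 1, "nig": 4, "niw": 6}


class DescriptorRegressor:
    """Feed-forward regressor over pair descriptors with optional heads."""

    def __init__(
        self,
        atomic_numbers: np.ndarray,
        head: str = "scalar",
        train_config: TrainConfig | None = None,
        with_charges: bool = False,
        seed: int = 0,
    ):
        if head not in HEAD_DIMS:
            raise ValueError(f"unknown head {head!r}")
        self.atomic_numbers = np.asarray(atomic_numbers, dtype=int)
        self.head = head
        self.config = train_config or TrainConfig()
        self.with_charges = with_charges
        self.seed = seed
        self.pairs = pair_table(len(self.atomic_numbers))
        probe = featurize(
            np.arange(len(self.atomic_numbers) * 3, dtype=float).reshape(-1, 3),
            self.config.descriptor,
            self.pairs,
        )
        self.n_features = probe.size
        self.norm = {
            "mu_x": np.zeros(self.n_features),
            "sd_x": np.ones(self.n_features),
            "mu_e": 0.0,
            "sd_e": 1.0,
        }
        rng = np.random.default_rng(seed)
        h1, h2 = self.config.hidden
        n_out = HEAD_DIMS[head] + (
            len(self.atomic_numbers) if with_charges else 0
        )
        d = self.n_features

        def glorot(n_in, n_out_):
            lim = np.sqrt(6.0 / (n_in + n_out_))
            return rng.uniform(-lim, lim, (n_in, n_out_))

        self.params = {
            "w1": glorot(d, h1),
            "b1": np.zeros(h1),
            "w2": glorot(h1, h2),
            "b2": np.zeros(h2),
            "w3": glorot(h2, n_out) * 0.1,
            "b3": np.zeros(n_out),
        }

    # -- forward ----------------------------------------------------------
    def _forward(self, xs: np.ndarray, jac: np.ndarray | None, params):
        """Graph forward pass on standardized descriptors.

        Returns a dict with 'out' (B, n_out), 'features' (B, h2), 'energy'
        (B,), and — when ``jac`` is given — 'forces' (B, 3n) via the exact
        input gradient of the mean energy output.
        """
        pt = {
            k: (v if isinstance(v, Tensor) else ad.constant(v))
            for k, v in params.items()
        }
        x = ad.constant(xs)
        z1 = x @ pt["w1"] + pt["b1"]
        a1 = ad.tanh(z1)
        z2 = a1 @ pt["w2"] + pt["b2"]
        a2 = ad.tanh(z2)
        out = a2 @ pt["w3"] + pt["b3"]
        energy = self.norm["mu_e"] + self.norm["sd_e"] * out[:, 0]
        result = {"out": out, "features": a2, "energy": energy}
        if jac is not None:
            # closed-form input gradient of the (pre-affine) energy output
            w3_e = pt["w3"][:, 0:1]  # (h2, 1)
            s2 = (1.0 - a2 * a2) * w3_e.T       # (B, h2)
            s1 = (s2 @ pt["w2"].T) * (1.0 - a1 * a1)  # (B, h1)
            g_std = s1 @ pt["w1"].T              # (B, d) d(out)/d(x_std)
            g_desc = g_std * (self.norm["sd_e"] / self.norm["sd_x"])
            result["forces"] = -ad.pair_contract(jac, g_desc)  # (B, 3n)
        if self.with_charges:
            n = len(self.atomic_numbers)
            result["charges"] = out[:, HEAD_DIMS[self.head]:HEAD_DIMS[self.head] + n]
        return result

    def _head_outputs(self, out):
        """Map raw head columns to evidential parameters (kcal/mol units)."""
        sd_e = self.norm["sd_e"]
        mu_e = self.norm["mu_e"]
        if self.head == "nig":
            return ev.NIGParams(
                gamma=mu_e + sd_e * out[:, 0],
                nu=ad.softplus(out[:, 1]) + 1e-6,
                alpha=1.0 + 1e-6 + ad.softplus(out[:, 2]),
                beta=(ad.softplus(out[:, 3]) + 1e-6) * sd_e**2,
            )
        if self.head == "niw":
            return ev.NIWOutput.from_raw(
                mu0=mu_e + sd_e * out[:, 0],
                mu1=out[:, 1],
                ell_raw=(out[:, 2], out[:, 3]),
                l21=out[:, 4],
                nu_raw=out[:, 5],
            )
        return None

    # -- data preparation ---------------------------------------------------
    def _descriptor_batch(self, structures):
        xs, jacs = [], []
        for s in structures:
            u, j = featurize(
                s, self.config.descriptor, self.pairs, with_jacobian=True
            )
            xs.append(u)
            jacs.append(j)
        return np.array(xs), np.array(jacs)

    def _standardize(self, x):
        return (x - self.norm["mu_x"]) / self.norm["sd_x"]

    # -- training -----------------------------------------------------------
    def _batch_loss(self, xs, jac, refs, params):
        cfg = self.config
        fwd = self._forward(xs, jac, params)
        if self.head == "scalar":
            loss = cfg.w_e * ad.absolute(fwd["energy"] - refs["energy"]).mean()
            loss = loss + cfg.w_f * ad.absolute(
                fwd["forces"] - refs["forces"]
            ).mean()
            if self.with_charges and "charge" in refs:
                q_tot = fwd["charges"].sum(axis=1)
                loss = loss + cfg.w_q * ad.absolute(
                    q_tot - refs["charge"]
                ).mean()
                if "dipole" in refs:
                    dip = EA_TO_DEBYE * ad.pair_contract(
                        refs["coords_t"], fwd["charges"]
                    )
                    loss = loss + cfg.w_d * ad.absolute(
                        dip - refs["dipole"]
                    ).mean()
            return loss
        lc = dataclasses.replace(
            cfg.nig_loss, w_f=cfg.w_f, w_q=cfg.w_q, w_d=cfg.w_d
        )
        pred = {"forces": fwd["forces"]}
        ref = {
            "energy": refs["energy"],
            "forces": refs["forces"],
        }
        if self.with_charges and "charge" in refs:
            q_tot = fwd["charges"].sum(axis=1)
            pred["charge"] = q_tot
            ref["charge"] = refs["charge"]
            if "dipole" in refs:
                pred["dipole"] = EA_TO_DEBYE * ad.pair_contract(
                    refs["coords_t"], fwd["charges"]
                )
                ref["dipole"] = refs["dipole"]
        if self.head == "nig":
            pred["params"] = self._head_outputs(fwd["out"])
            if cfg.loss_variant == "derl":
                return ev.derl_total_loss(pred, ref, lc)
            return ev.ders_total_loss(pred, ref, lc)
        # niw
        out = self._head_outputs(fwd["out"])
        extra_pred = {k: v for k, v in pred.items() if k in ("forces", "dipole")}
        extra_ref = {k: v for k, v in ref.items() if k in ("forces", "dipole")}
        return ev.derm_loss(
            out,
            refs["energy"],
            refs.get("charge", np.zeros_like(refs["energy"])),
            lc,
            pred_extra=extra_pred,
            ref_extra=extra_ref,
        )

    def _references(self, structures):
        refs = {
            "energy": np.array([s.energy for s in structures]),
            "forces": np.array([s.forces.ravel() for s in structures]),
        }
        if self.with_charges and all(
            s.total_charge is not None for s in structures
        ):
            refs["charge"] = np.array([s.total_charge for s in structures])
            # (B, n_atoms, 3): maps atomic charges to the dipole vector
            refs["coords_t"] = np.array([s.coordinates for s in structures])
            if all(s.dipole is not None for s in structures):
                refs["dipole"] = np.array([s.dipole for s in structures])
        return refs

    def fit(self, dataset: Dataset):
        """Train on the dataset's train split, early-stop on validation."""
        cfg = self.config
        tr_idx = dataset.indices("train")
        va_idx = dataset.indices("validation")
        if len(tr_idx) == 0 or len(va_idx) == 0:
            raise ValueError("dataset needs train and validation splits")
        train = [dataset[i] for i in tr_idx]
        val = [dataset[i] for i in va_idx]
        x_tr, jac_tr = self._descriptor_batch(train)
        x_va, jac_va = self._descriptor_batch(val)
        e_tr = np.array([s.energy for s in train])
        self.norm["mu_x"] = x_tr.mean(0)
        self.norm["sd_x"] = x_tr.std(0) + 1e-10
        self.norm["mu_e"] = float(e_tr.mean())
        self.norm["sd_e"] = float(e_tr.std() + 1e-10)
        xs_tr = self._standardize(x_tr)
        xs_va = self._standardize(x_va)
        refs_tr = self._references(train)
        refs_va = self._references(val)

        rng = np.random.default_rng(self.seed + 7)
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        ema = {k: v.copy() for k, v in self.params.items()}
        best = {k: v.copy() for k, v in self.params.items()}
        best_val = np.inf
        patience = 0
        step = 0
        history = []
        n = len(train)
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pt = {k: Tensor(v) for k, v in self.params.items()}
                refs_b = {
                    k: v[idx] for k, v in refs_tr.items()
                }
                loss = self._batch_loss(xs_tr[idx], jac_tr[idx], refs_b, pt)
                if not np.isfinite(loss.value):
                    logger.warning(
                        "non-finite loss at epoch %d; restoring best", epoch
                    )
                    self.params = best
                    return history
                loss.backward()
                lr = cfg.learning_rate * cfg.lr_decay ** (
                    step // cfg.lr_decay_steps
                )
                step += 1
                for k in self.params:
                    g = pt[k].grad
                    adam_m[k] = 0.9 * adam_m[k] + 0.1 * g
                    adam_v[k] = 0.999 * adam_v[k] + 0.001 * g * g
                    mhat = adam_m[k] / (1 - 0.9**step)
                    vhat = adam_v[k] / (1 - 0.999**step)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
                    if cfg.ema:
                        ema[k] = (
                            cfg.ema_decay * ema[k]
                            + (1 - cfg.ema_decay) * self.params[k]
                        )
                epoch_loss += float(loss.value)
                n_batches += 1
            if epoch % cfg.validation_every == 0:
                eval_params = ema if cfg.ema else self.params
                pt = {k: ad.constant(v) for k, v in eval_params.items()}
                vloss = float(
                    value_of(self._batch_loss(xs_va, jac_va, refs_va, pt))
                )
                history.append(
                    {
                        "epoch": epoch,
                        "train_loss": epoch_loss / max(n_batches, 1),
                        "val_loss": vloss,
                    }
                )
                if vloss < best_val - 1e-12:
                    best_val = vloss
                    best = {k: v.copy() for k, v in eval_params.items()}
                    patience = 0
                else:
                    patience += 1
                    if patience >= cfg.early_stopping_patience:
                        break
        self.params = best
        self.history = history
        self.best_val_loss = best_val
        return history

    # -- inference ----------------------------------------------------------
    def predict(self, structures) -> list[PredictionRecord]:
        """Predictions with exact analytic forces and pooled features."""
        if isinstance(structures, Dataset):
            structures = list(structures)
        single = isinstance(structures, Structure)
        if single:
            structures = [structures]
        for s in structures:
            if not np.array_equal(s.atomic_numbers, self.atomic_numbers):
                raise ValueError("composition mismatch with the trained model")
        x, jac = self._descriptor_batch(structures)
        xs = self._standardize(x)
        pt = {k: ad.constant(v) for k, v in self.params.items()}
        fwd = self._forward(xs, jac, pt)
        energies = value_of(fwd["energy"])
        forces = value_of(fwd["forces"]).reshape(len(structures), -1, 3)
        features = value_of(fwd["features"])
        head_out = self._head_outputs(fwd["out"])
        records = []
        for b, s in enumerate(structures):
            ho = None
            if self.head == "nig":
                ho = ev.NIGParams(
                    gamma=float(value_of(head_out.gamma)[b]),
                    nu=float(value_of(head_out.nu)[b]),
                    alpha=float(value_of(head_out.alpha)[b]),
                    beta=float(value_of(head_out.beta)[b]),
                )
                energy = ho.gamma
            elif self.head == "niw":
                ho = ev.NIWOutput(
                    mu0=float(value_of(head_out.mu0)[b]),
                    mu1=float(value_of(head_out.mu1)[b]),
                    l00=float(value_of(head_out.l00)[b]),
                    l10=float(value_of(head_out.l10)[b]),
                    l11=float(value_of(head_out.l11)[b]),
                    nu=float(value_of(head_out.nu)[b]),
                )
                energy = ho.mu0
            else:
                energy = float(energies[b])
            charge = dipole = None
            if self.with_charges:
                q = value_of(fwd["charges"])[b]
                charge = float(q.sum())
                dipole = EA_TO_DEBYE * q @ s.coordinates
            records.append(
                PredictionRecord(
                    energy=float(energy),
                    forces=forces[b],
                    features=features[b],
                    head_outputs=ho,
                    charge=charge,
                    dipole=dipole,
                )
            )
        return records[0] if single else records

    def as_provider(self):
        """A coords -> (energy, forces) callable for the dynamics module."""

        def provider(coords):
            s = Structure(
                atomic_numbers=self.atomic_numbers,
                coordinates=np.asarray(coords, dtype=float),
            )
            rec = self.predict(s)
            return rec.energy, rec.forces

        return provider

    # -- persistence ----------------------------------------------------------
    def save(self, path):
        meta = {
            "head": self.head,
            "with_charges": self.with_charges,
            "seed": self.seed,
            "atomic_numbers": self.atomic_numbers.tolist(),
            "hidden": list(self.config.hidden),
            "n_gaussians": self.config.descriptor.n_gaussians,
        }
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            **{f"p_{k}": v for k, v in self.params.items()},
            **{f"n_{k}": np.asarray(v) for k, v in self.norm.items()},
        )

    @classmethod
    def load(cls, path) -> "DescriptorRegressor":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = TrainConfig(
                hidden=tuple(meta["hidden"]),
                descriptor=DescriptorConfig(n_gaussians=meta["n_gaussians"]),
            )
            model = cls(
                atomic_numbers=np.array(meta["atomic_numbers"]),
                head=meta["head"],
                train_config=cfg,
                with_charges=meta["with_charges"],
                seed=meta["seed"],
            )
            model.params = {
                k[2:]: data[k].copy() for k in data.files if k.startswith("p_")
            }
            model.norm = {
                k[2:]: (
                    float(data[k]) if data[k].ndim == 0 else data[k].copy()
                )
                for k in data.files
                if k.startswith("n_")
            }
        return model


# ---------------------------------------------------------------------------
# high-level API
# ---------------------------------------------------------------------------

def train_model(
    dataset: Dataset,
    train_config: TrainConfig | None = None,
    head: str = "scalar",
    seed: int = 0,
    with_charges: bool | None = None,
) -> DescriptorRegressor:
    """Train one model on the dataset's train/validation splits."""
    if with_charges is None:
        with_charges = all(s.total_charge is not None for s in dataset)
    model = DescriptorRegressor(
        atomic_numbers=dataset.atomic_numbers,
        head=head,
        train_config=train_config,
        with_charges=with_charges,
        seed=seed,
    )
    model.fit(dataset)
    return model


def predict(model: DescriptorRegressor, structures):
    return model.predict(structures)


def train_ensemble(
    dataset: Dataset,
    train_config: TrainConfig | None = None,
    n_members: int = 6,
    seed: int = 0,
    head: str = "scalar",
    paired_splits: bool = True,
) -> list[DescriptorRegressor]:
    """Train a query-by-committee ensemble.

    Members differ in parameter initialization and in the train/validation
    shuffle. With ``paired_splits`` (default) members 2k and 2k+1 share one
    shuffle and differ only in initialization, mirroring the reference
    protocol where models 1/2, 3/4 and 5/6 were trained on identical data.
    """
    from .chemio import split_dataset

    if n_members < 2:
        raise ValueError("a committee needs at least 2 members")
    models = []
    failures = []
    for k in range(n_members):
        split_seed = seed * 1000 + (k // 2 if paired_splits else k)
        init_seed = seed * 1000 + 500 + k
        member_ds = split_dataset(dataset, 0.8, seed=split_seed)
        try:
            models.append(
                train_model(member_ds, train_config, head=head, seed=init_seed)
            )
        except Exception as err:  # noqa: BLE001 - collected and re-raised
            failures.append((k, init_seed, str(err)))
    if failures:
        raise RuntimeError(f"ensemble members failed: {failures}")
    return models


def select_committee(models, which="ens3"):
    """Sub-committee selection; "ens3" takes members 1, 3, 5 of six."""
    if which == "ens6":
        return list(models)
    if which == "ens3":
        return list(models[0::2])
    return [models[i] for i in which]


def ensemble_predict(models, structures):
    """Per-structure committee statistics (mean energy, σ_E)."""
    all_e = np.array(
        [[r.energy for r in m.predict(structures)] for m in models]
    )  # (M, B)
    return [ensemble_statistics(all_e[:, b]) for b in range(all_e.shape[1])]
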