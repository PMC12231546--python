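"""Synthetic two-stream disorder datasets.

The generator emulates the structure of the real task — proteins with
segmental order/disorder, a "traditional" feature stream and a "PLM" feature
stream — while making the *interaction* of the streams, not either stream
alone, carry the label signal. Per residue j of a protein:

* a two-state Markov chain proposes a segment state s_j (ordered/disordered)
  with entry probability ``p_enter`` and exit probability ``p_exit``;
* two latent signals u_j, v_j follow independent stationary AR(1) chains with
  smoothing ``rho`` and standard-normal innovations (marginal s.d.
  1/sqrt(1 - rho^2), ~1.67 at the default rho = 0.8);
* the true disorder probability is
  ``pi_j = logistic(beta_b*u_j + beta_p*v_j + beta*u_j*v_j + gamma*[s_j=1])``
  and the label is Bernoulli(pi_j);
* stream R_b carries u_j in its first ``b_signal_width`` columns plus
  N(0, sigma^2) noise, stream R_p carries v_j likewise; all remaining columns
  are pure N(0, 1) noise;
* a fraction ``unlabeled_frac`` of residues is relabeled UNLABELED uniformly
  at random, mimicking residues with no experimental annotation.

The latent signals (u, v, s, pi) are retained on the dataset object so tests
can compute the Bayes-optimal score — the performance ceiling of any model —
but they are never written to the feature files a model reads. With
``beta > 0`` and ``beta_b = beta_p = 0`` either single stream is useless
(AUC ~ 0.5) while both together separate well: the construction that makes
feature fusion necessary rather than convenient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    DISORDERED, ORDERED, UNLABELED,
    AMINO_ACIDS, ProteinRecord,
)

__all__ = [
    "SimulationParams",
    "SyntheticDataset",
    "simulate_dataset",
    "bayes_scores",
    "make_toy_pssm",
    "apply_unlabeled_mask",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generator configuration; defaults define the package's study conditions."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (50, 150)
    p_enter: float = 0.05
    p_exit: float = 0.10
    beta: float = 3.0       # interaction coefficient (u*v)
    beta_b: float = 0.5     # marginal coefficient of the traditional latent
    beta_p: float = 0.5     # marginal coefficient of the PLM latent
    gamma: float = 1.0      # segment-state bias on the disorder logit
    sigma: float = 0.5      # feature noise s.d. on signal columns
    rho: float = 0.8        # AR(1) smoothing of the latent signals
    b_dim: int = 80         # traditional stream width
    p_dim: int = 64         # PLM stream width (study-scale stand-in for D_p)
    b_signal_width: int = 8
    p_signal_width: int = 8
    unlabeled_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_enter < 1 and 0 < self.p_exit < 1):
            raise ValueError("transition probabilities must lie in (0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.unlabeled_frac < 1:
            raise ValueError("unlabeled_frac must lie in [0, 1)")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if (self.b_signal_width > self.b_dim
                or self.p_signal_width > self.p_dim):
            raise ValueError("signal width exceeds stream width")


@dataclass
class SyntheticDataset:
    """Generated records, labels, feature streams and retained latents."""

    params: SimulationParams
    records: list[ProteinRecord]
    labels: list[np.ndarray]          # int8 over {ORDERED, DISORDERED, UNLABELED}
    R_b: list[np.ndarray]             # (L, b_dim) each
    R_p: list[np.ndarray]             # (L, p_dim) each
    latent_u: list[np.ndarray] | None = None
    latent_v: list[np.ndarray] | None = None
    latent_s: list[np.ndarray] | None = None
    latent_pi: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.records)


def _ar1(rng: np.random.Generator, L: int, rho: float) -> np.ndarray:
    """Stationary AR(1) chain with standard-normal innovations."""
    x = np.empty(L)
    x[0] = rng.standard_normal() / np.sqrt(1.0 - rho**2)
    innov = rng.standard_normal(L)
    for t in range(1, L):
        x[t] = rho * x[t - 1] + innov[t]
    return x


def _segments(rng: np.random.Generator, L: int, p_enter: float,
              p_exit: float) -> np.ndarray:
    """Two-state Markov chain started from its stationary distribution."""
    stat_dis = p_enter / (p_enter + p_exit)
    s = np.empty(L, dtype=np.int8)
    s[0] = rng.random() < stat_dis
    u = rng.random(L)
    for t in range(1, L):
        s[t] = (u[t] < p_enter) if s[t - 1] == 0 else (u[t] >= p_exit)
    return s


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Draw a full dataset; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    records, labels = [], []
    R_b_all, R_p_all = [], []
    us, vs, ss, pis = [], [], [], []
    wb, wp = params.b_signal_width, params.p_signal_width
    for i in range(params.n_proteins):
        L = int(rng.integers(params.length_range[0],
                             params.length_range[1] + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        records.append(ProteinRecord(id=f"syn{i:04d}", sequence=seq))

        s = _segments(rng, L, params.p_enter, params.p_exit)
        u = _ar1(rng, L, params.rho)
        v = _ar1(rng, L, params.rho)
        logit = (params.beta_b * u + params.beta_p * v
                 + params.beta * u * v + params.gamma * s)
        # keep the oracle score strictly inside (0, 1) under float saturation
        pi = np.clip(_sigmoid(logit), 1e-12, 1.0 - 1e-12)
        y = (rng.random(L) < pi).astype(np.int8)
        lab = np.where(y == 1, DISORDERED, ORDERED).astype(np.int8)
        lab = apply_unlabeled_mask(lab, params.unlabeled_frac,
                                   seed=int(rng.integers(2**31)))

        Rb = rng.standard_normal((L, params.b_dim))
        Rb[:, :wb] = u[:, None] + params.sigma * rng.standard_normal((L, wb))
        Rp = rng.standard_normal((L, params.p_dim))
        Rp[:, :wp] = v[:, None] + params.sigma * rng.standard_normal((L, wp))

        labels.append(lab)
        R_b_all.append(Rb)
        R_p_all.append(Rp)
        us.append(u); vs.append(v); ss.append(s); pis.append(pi)

    return SyntheticDataset(
        params=params, records=records, labels=labels,
        R_b=R_b_all, R_p=R_p_all,
        latent_u=us, latent_v=vs, latent_s=ss, latent_pi=pis,
    )


def bayes_scores(dataset: SyntheticDataset) -> list[np.ndarray]:
    """The generator's own true disorder probabilities pi_j per protein.

    This is the Bayes-optimal score — an upper bound on the ranking
    performance of any model trained on the generated features.
    """
    if dataset.latent_pi is None:
        raise ValueError("dataset does not retain latent signals")
    return [pi.copy() for pi in dataset.latent_pi]


def single_stream_bayes_scores(dataset: SyntheticDataset,
                               stream: str) -> list[np.ndarray]:
    """Best score using only one latent stream (the other integrated out).

    Monte-Carlo expectation of pi over the unobserved latent; used to show
    that under a pure interaction (beta_b = beta_p = 0) either stream alone
    is uninformative.
    """
    if dataset.latent_u is None:
        raise ValueError("dataset does not retain latent signals")
    p = dataset.params
    rng = np.random.default_rng(p.seed + 1)
    zs = rng.standard_normal(512)
    out = []
    for u, v, s in zip(dataset.latent_u, dataset.latent_v, dataset.latent_s):
        if stream == "traditional":
            lat, coef_own, coef_other = u, p.beta_b, p.beta_p
        elif stream == "plm":
            lat, coef_own, coef_other = v, p.beta_p, p.beta_b
        else:
            raise ValueError("stream must be 'traditional' or 'plm'")
        # E_z[ logistic(coef_own*lat + (coef_other + beta*lat) z + gamma s) ]
        lin = coef_own * lat[:, None] + p.gamma * s[:, None] \
            + (coef_other + p.beta * lat[:, None]) * zs[None, :]
        out.append(_sigmoid(lin).mean(axis=1))
    return out


def apply_unlabeled_mask(labels: np.ndarray, fraction: float,
                         seed: int) -> np.ndarray:
    """Flip exactly round(fraction * n_labeled) labeled residues to UNLABELED."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    labels = np.asarray(labels, dtype=np.int8).copy()
    labeled_idx = np.flatnonzero(labels != UNLABELED)
    k = int(round(fraction * len(labeled_idx)))
    if k:
        rng = np.random.default_rng(seed)
        flip = rng.choice(labeled_idx, size=k, replace=False)
        labels[flip] = UNLABELED
    return labels


def make_toy_pssm(record: ProteinRecord, seed: int) -> str:
    """A syntactically valid PSI-BLAST ``-out_ascii_pssm`` text for fixtures.

    Seeded integer log-odds in [-10, 10], the percentage block, and the
    per-row trailing statistics the real tool emits.
    """
    rng = np.random.default_rng(seed)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, observed"
        " percentages rounded down, information per position, and relative"
        " weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    for i, aa in enumerate(record.sequence, start=1):
        logodds = rng.integers(-10, 11, size=20)
        perc = rng.integers(0, 101, size=20)
        row = (f"{i:5d} {aa} " + " ".join(f"{v:3d}" for v in logodds)
               + "  " + " ".join(f"{v:3d}" for v in perc)
               + f"  {rng.random():.2f} {rng.random():.2f}")
        lines.append(row)
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1373     0.3179",
        "",
    ]
    return "\n".join(lines)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset as portable files: FASTA, labels, features, params.

    ``sequences.fasta`` + ``labels.fasta`` (label strings over {0,1,-}) are
    plain text; per-protein feature matrices go into ``features.npz`` under
    keys ``Rb_<id>`` / ``Rp_<id>``; the generator parameters are echoed to
    ``params.yaml``.
    """
    import yaml

    from .io import write_fasta, write_labels_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, outdir / "sequences.fasta")
    write_labels_fasta(
        {r.id: lab for r, lab in zip(dataset.records, dataset.labels)},
        outdir / "labels.fasta",
    )
    arrays = {}
    for rec, Rb, Rp in zip(dataset.records, dataset.R_b, dataset.R_p):
        arrays[f"Rb_{rec.id}"] = Rb
        arrays[f"Rp_{rec.id}"] = Rp
    np.savez(outdir / "features.npz", **arrays)
    params = asdict(dataset.params)
    params["length_range"] = list(params["length_range"])
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def load_dataset(outdir: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset` (no latents)."""
    import yaml

    from .io import read_fasta, read_labels

    outdir = Path(outdir)
    with open(outdir / "params.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["length_range"] = tuple(raw["length_range"])
    params = SimulationParams(**raw)
    records = read_fasta(outdir / "sequences.fasta")
    labels = read_labels(outdir / "labels.fasta", dialect="fasta_aligned",
                         sequences={r.id: r.sequence for r in records})
    with np.load(outdir / "features.npz") as z:
        R_b = [z[f"Rb_{r.id}"] for r in records]
        R_p = [z[f"Rp_{r.id}"] for r in records]
    return SyntheticDataset(
        params=params, records=records,
        labels=[labels[r.id] for r in records], R_b=R_b, R_p=R_p,
    )
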