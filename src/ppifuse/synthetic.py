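"""Synthetic benchmark generator with a planted, recoverable pair signal.

The generator emulates the statistical structure the prediction method
assumes, so every stage is testable without external downloads:

- Proteins belong to latent functional groups. Each group has its own
  residue-frequency profile, and sequences are drawn from it with short
  run-length repeats, so both the mean physicochemical profile and the
  lag auto-covariances carry group information.
- Each namespace's ontology is a rooted DAG with one subtree ("functional
  module") per group under the root; within a module, nodes attach to one
  or two existing module members, producing diamonds. A protein's
  annotations are drawn mostly from its own group's module.
- Pair labels are Bernoulli with interaction probability
  logistic(beta0 + beta_sig * z), where z is the sum of the standardized
  shared-annotation count and the standardized correlation of the two
  proteins' mean physicochemical profiles; beta0 is solved by bisection so
  the expected positive fraction matches the configuration. With
  beta_sig = 0 the labels are independent of every feature.

Everything is deterministic given the seed: regenerating with the same
configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from ppifuse import io_formats
from ppifuse.go_features import GoDag
from ppifuse.io_formats import AnnotationTable, Pair, PairList, ProteinRecord
from ppifuse.physchem import ScaleTable, residue_encode

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic benchmark."""

    n_proteins: int = 120
    length_range: tuple[int, int] = (150, 400)
    n_pairs: int = 400
    positive_fraction: float = 0.5
    dag_size: int = 60  # terms per namespace, root included
    terms_per_protein: tuple[int, int] = (6, 12)
    beta_sig: float = 3.0
    n_groups: int = 3
    group_annotation_bias: float = 0.95
    namespaces: tuple[str, ...] = DEFAULT_NAMESPACES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 3 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive fraction must be in (0, 1)")
        if self.beta_sig < 0:
            raise ValueError("beta_sig must be >= 0")
        if self.dag_size < 1 + self.n_groups:
            raise ValueError("dag_size must fit the root plus one module seed per group")
        if min(self.n_proteins, self.n_pairs, self.n_groups) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class Universe:
    """Generated proteins, ontology, annotations and the latent group structure."""

    proteins: list[ProteinRecord]
    dag: GoDag
    annotations: AnnotationTable
    groups: dict[str, int]
    term_relations: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)
    config: SynthConfig | None = None


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _draw_sequence(length: int, profile: np.ndarray, rng: np.random.Generator) -> str:
    # run-length repeats plant short-range autocorrelation for the AC features
    out: list[str] = []
    while len(out) < length:
        residue = rng.choice(AMINO_ACIDS, p=profile)
        run = 1 + int(rng.random() < 0.5) + int(rng.random() < 0.2)
        out.extend([residue] * run)
    return "".join(out[:length])


def generate_universe(config: SynthConfig) -> Universe:
    """Generate proteins, one modular DAG per namespace, and group-biased annotations."""
    rng = np.random.default_rng(config.seed)
    n_groups = config.n_groups

    group_of = {
        f"P{i:04d}": int(g)
        for i, g in enumerate(rng.permutation(np.arange(config.n_proteins) % n_groups))
    }
    profiles = np.vstack([_softmax(rng.normal(0.0, 0.8, 20)) for _ in range(n_groups)])

    lmin, lmax = config.length_range
    proteins = [
        ProteinRecord(pid, _draw_sequence(int(rng.integers(lmin, lmax + 1)), profiles[g], rng))
        for pid, g in sorted(group_of.items())
    ]

    edges: list[tuple[str, str]] = []
    relations: dict[tuple[str, str], str] = {}
    namespaces: dict[str, str] = {}
    module_terms: dict[str, list[list[str]]] = {}
    all_terms: list[str] = []
    for ns_idx, ns in enumerate(config.namespaces):
        base = 1_000_000 * (ns_idx + 1)
        ids = [f"GO:{base + i:07d}" for i in range(config.dag_size)]
        root, module_seeds = ids[0], ids[1 : 1 + n_groups]
        for term in ids:
            namespaces[term] = ns
        members: list[list[str]] = [[seed] for seed in module_seeds]
        for seed in module_seeds:
            edges.append((seed, root))
            relations[(seed, root)] = "is_a"
        for term in ids[1 + n_groups :]:
            g = int(rng.integers(n_groups))
            n_parents = 1 + int(rng.random() < 0.3 and len(members[g]) > 1)
            parents = rng.choice(members[g], size=min(n_parents, len(members[g])), replace=False)
            for parent in parents:
                edges.append((term, parent))
                relations[(term, parent)] = "part_of" if rng.random() < 0.25 else "is_a"
            members[g].append(term)
        module_terms[ns] = members
        all_terms.extend(ids[1:])  # roots are never annotated directly

    dag = GoDag(edges, namespaces)

    kmin, kmax = config.terms_per_protein
    annotations: dict[str, set[str]] = {}
    ns_list = list(config.namespaces)
    for record in proteins:
        g = group_of[record.id]
        k = int(rng.integers(kmin, kmax + 1))
        terms: set[str] = set()
        for _ in range(k):
            if rng.random() < config.group_annotation_bias:
                ns = ns_list[int(rng.integers(len(ns_list)))]
                pool = module_terms[ns][g]
                terms.add(str(rng.choice(pool)))
            else:
                terms.add(str(rng.choice(all_terms)))
        annotations[record.id] = terms

    table = AnnotationTable(annotations, namespaces)
    return Universe(
        proteins=proteins,
        dag=dag,
        annotations=table,
        groups=group_of,
        term_relations=relations,
        config=config,
    )


def pair_signal(
    universe: Universe, pair_keys: Sequence[tuple[str, str]], scales: ScaleTable | None = None
) -> np.ndarray:
    """The planted signal z per pair: standardized shared-term count plus
    standardized mean-physicochemical-profile correlation."""
    scales = scales or ScaleTable.bundled()
    profile = {
        p.id: residue_encode(p, scales).mean(axis=0) for p in universe.proteins
    }
    mat = np.vstack([profile[p.id] for p in universe.proteins])
    mu, sd = mat.mean(axis=0), mat.std(axis=0)
    sd[sd == 0] = 1.0
    zprof = {p.id: (profile[p.id] - mu) / sd for p in universe.proteins}

    shared = np.array(
        [
            len(universe.annotations.terms_for(u) & universe.annotations.terms_for(v))
            for u, v in pair_keys
        ],
        dtype=float,
    )
    corr = np.array(
        [float(np.corrcoef(zprof[u], zprof[v])[0, 1]) for u, v in pair_keys]
    )
    corr[~np.isfinite(corr)] = 0.0
    return _standardize(shared) + _standardize(corr)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_pairs(universe: Universe, config: SynthConfig | None = None) -> PairList:
    """Sample labeled pairs with interaction probability logistic(beta0 + beta_sig * z)."""
    config = config or universe.config
    rng = np.random.default_rng(config.seed + 1)
    ids = [p.id for p in universe.proteins]
    n = len(ids)
    total = n * (n - 1) // 2
    if config.n_pairs > total:
        raise ValueError(f"requested {config.n_pairs} pairs but only {total} are available")
    flat = rng.choice(total, size=config.n_pairs, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    keys = [(ids[iu[f]], ids[ju[f]]) for f in sorted(flat)]

    if config.beta_sig == 0:
        probs = np.full(len(keys), config.positive_fraction)
    else:
        z = pair_signal(universe, keys)
        target = config.positive_fraction

        def excess(b0: float) -> float:
            return float(np.mean(expit(b0 + config.beta_sig * z))) - target

        beta0 = brentq(excess, -50.0, 50.0, xtol=1e-10)
        probs = expit(beta0 + config.beta_sig * z)
    labels = (rng.random(len(keys)) < probs).astype(int)
    rows = [Pair.canonical(u, v, int(lab)) for (u, v), lab in zip(keys, labels)]
    return PairList(rows)


def write_fixture_dir(universe: Universe, pairs: PairList, outdir: str | Path) -> dict[str, Path]:
    """Write the standard pipeline input files (FASTA, OBO, TSVs) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "pairs": outdir / "pairs.tsv",
    }
    io_formats.write_fasta(universe.proteins, paths["fasta"])
    _write_obo(universe, paths["obo"])
    io_formats.write_annotations(universe.annotations, paths["annotations"])
    io_formats.write_pairs(pairs, paths["pairs"])
    return paths


def _write_obo(universe: Universe, path: Path) -> None:
    dag = universe.dag
    lines = ["format-version: 1.2", ""]
    for term in dag.nodes:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        lines.append(f"namespace: {dag.namespace(term)}")
        for parent in dag.parents(term):
            relation = universe.term_relations.get((term, parent), "is_a")
            if relation == "is_a":
                lines.append(f"is_a: {parent} ! synthetic term {parent}")
            else:
                lines.append(f"relationship: part_of {parent} ! synthetic term {parent}")
        lines.append("")
    path.write_text("\n".join(lines))
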