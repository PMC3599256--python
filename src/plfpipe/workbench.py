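"""Synthetic data generation and end-to-end likelihood runs.

The generator draws a random rooted binary topology (uniform sequential
pair joins), exponential branch lengths, and evolves nucleotide
sequences site-independently down the tree with the same eigen-system
transition matrices the likelihood engine uses.  Defaults mirror the
hardware's load-balancing convention of site counts that are multiples
of 128; an arbitrary length is allowed for the software path.

Substitution models: Jukes-Cantor (uniform rates and frequencies) or a
random reversible (GTR-style) model with Dirichlet base frequencies and
gamma exchangeabilities, rate-normalised to one expected substitution
per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from . import beagle_api as api
from .plf_kernel import NumericMode, ValidationError

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset",
           "random_reversible_eigen_system", "run_end_to_end", "end_to_end"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Branch lengths are exponential with mean 0.1 substitutions/site
    (typical of curated nucleotide phylogenies); site counts default to
    the hardware-friendly multiple of 128.
    """

    n_taxa: int = 8
    n_sites: int = 128
    branch_length_mean: float = 0.1
    model: str = "jc69"  # jc69 | rev
    seed: int = 0


@dataclass
class SyntheticDataset:
    newick: str
    alignment: dict[str, str]
    eigen: api.EigenSystem
    pi: np.ndarray
    tree: api.Tree


def random_reversible_eigen_system(rng) -> tuple[api.EigenSystem, np.ndarray]:
    """Random reversible rate matrix: pi ~ Dirichlet(5), exchangeabilities
    ~ Gamma(2, 1/2), Q_ij = s_ij pi_j, normalised to unit mean rate."""
    pi = rng.dirichlet(np.full(4, 5.0))
    s = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    s[iu] = rng.gamma(2.0, 0.5, size=len(iu[0]))
    s = s + s.T
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.sum(pi * np.diag(q))
    q /= rate
    return api.reversible_eigen_system(q, pi), pi


def _random_topology(n_taxa: int, rng) -> tuple[str, list]:
    """Random rooted binary topology by uniform sequential pair joins;
    returns nested (name-or-children, length placeholder) structure."""
    forest = [[f"t{i+1}", None] for i in range(n_taxa)]
    while len(forest) > 1:
        i, j = sorted(rng.choice(len(forest), size=2, replace=False))
        b = forest.pop(j)
        a = forest.pop(i)
        forest.append([[a, b], None])
    return forest[0]


def _assign_lengths(node, rng, mean):
    node[1] = float(rng.exponential(mean))
    if isinstance(node[0], list):
        for child in node[0]:
            _assign_lengths(child, rng, mean)


def _to_newick(node, root=True) -> str:
    label, length = node
    if isinstance(label, list):
        body = "(" + ",".join(_to_newick(c, root=False) for c in label) + ")"
    else:
        body = label
    return body + ";" if root else f"{body}:{length:.10g}"


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Deterministic-under-seed tree + alignment + model bundle."""
    if spec.n_taxa < 2:
        raise ValidationError("need at least two taxa")
    if spec.n_sites < 1:
        raise ValidationError("need at least one site")
    rng = np.random.default_rng(spec.seed)
    top = _random_topology(spec.n_taxa, rng)
    _assign_lengths(top, rng, spec.branch_length_mean)
    newick = _to_newick(top)
    tree = api.parse_newick(newick)

    if spec.model == "jc69":
        eigen, pi = api.jc69_eigen_system(), np.full(4, 0.25)
    elif spec.model == "rev":
        eigen, pi = random_reversible_eigen_system(rng)
    else:
        raise ValidationError(f"unknown model {spec.model!r}")

    # evolve states down the tree, vectorised over sites
    states: dict[int, np.ndarray] = {}
    states[tree.root_id] = rng.choice(4, size=spec.n_sites, p=pi)
    for parent, left, right in reversed(tree.postorder_ops):
        for child in (left, right):
            t = tree.nodes[child].length
            p = api.transition_probability(eigen, t).p
            u = rng.random(spec.n_sites)
            cum = np.cumsum(p[states[parent]], axis=1)
            states[child] = np.minimum((u[:, None] > cum).sum(axis=1), 3)
    bases = np.array(list("ACGT"))
    alignment = {tree.nodes[i].name: "".join(bases[states[i]]) for i in tree.tip_ids}
    return SyntheticDataset(newick=newick, alignment=alignment, eigen=eigen,
                            pi=pi, tree=tree)


def end_to_end(tree: api.Tree, alignment: dict[str, str], eigen: api.EigenSystem,
               pi, mode: NumericMode) -> float:
    """One full API call sequence: set data, update transition matrices,
    update partials over the traversal, root log-likelihood."""
    names = tree.tip_names()
    missing = [n for n in names if n not in alignment]
    if missing:
        raise ValidationError(f"alignment is missing taxa {missing}")
    patterns, weights = api.compress_patterns([alignment[n] for n in names])
    inst = api.create_instance(tree.n_tips, len(weights.w), mode)
    api.set_instance_data(inst, patterns, pi, weights.w)
    api.update_all_transition_matrices(inst, eigen, tree)
    api.update_partials(inst, tree)
    return api.calculate_root_log_likelihood(inst, tree)


def run_end_to_end(tree_file, alignment_file, mode: str = "both",
                   report_path=None, model: str = "jc69",
                   eigen: api.EigenSystem | None = None, pi=None,
                   aln_format: str = "fasta") -> dict:
    """File-level driver; returns (and optionally writes) the report.

    ``mode`` is ``exact``, ``device`` or ``both``; with ``both`` the
    report additionally carries the relative deviation of the
    single-precision device path from the double-precision exact path.
    """
    try:
        with open(tree_file) as fh:
            tree = api.parse_newick(fh.read())
    except OSError as exc:
        raise ValidationError(f"{tree_file}: {exc}") from exc
    alignment = api.read_alignment(alignment_file, aln_format)
    if eigen is None:
        if model != "jc69":
            raise ValidationError("only the jc69 model is built in; pass an "
                                  "eigen-system for other models")
        eigen, pi = api.jc69_eigen_system(), np.full(4, 0.25)

    report: dict = {
        "tree_file": str(tree_file),
        "alignment_file": str(alignment_file),
        "n_taxa": tree.n_tips,
        "n_sites": len(next(iter(alignment.values()))),
    }
    modes = [NumericMode.EXACT, NumericMode.DEVICE] if mode == "both" \
        else [NumericMode(mode)]
    for m in modes:
        report[f"lnL_{m.value}"] = end_to_end(tree, alignment, eigen, pi, m)
    if mode == "both":
        exact, device = report["lnL_exact"], report["lnL_device"]
        report["relative_deviation"] = abs(device - exact) / abs(exact)
    if report_path is not None:
        with open(report_path, "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=True)
    return report
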