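"""Synthetic cohort generator with planted ground truth.

Emulates the four pipeline inputs for a case/control transcriptomic study
whose raw data are not available: a log2 expression matrix, a
protein-protein interaction edge list, the three regulatory pair tables
and a gene-set collection. Everything is planted so downstream stages are
testable by recovery:

* differential expression — a fraction of features is shifted in cases by
  ``log2(FC)`` with i.i.d. Gaussian log2 noise (log-normal intensities,
  the standard microarray approximation);
* dense modules — disjoint near-cliques (bounded edge dropout, every
  member keeping within-module degree >= 4) over planted DE coding genes,
  on top of sparse background edges;
* regulatory chains — "driver" lncRNAs reach every planted module through
  lncRNA->miRNA->gene chains, while four decoy lncRNAs each fail exactly
  one stage of the prioritization cascade:

  - ``fc``      modulated below the |FC| >= 4 bar (but still a DEG),
  - ``mirna``   no validated miRNA interaction,
  - ``deg``     miRNA targets that miss the DEG set entirely,
  - ``coverage`` chains confined to a strict subset of the modules.

All randomness flows from one root seed: ``SeedSequence(seed)`` is split
into fixed, named child streams (truth, matrix, network, regulatory,
gene sets), so each artifact is reproducible bit-for-bit and independent
of the order in which the generators are called.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as io_formats
from .data import (
    CODING,
    LNCRNA,
    ExpressionMatrix,
    GeneSetCollection,
    RegulatoryAnnotation,
)
from .errors import ConfigError

DECOY_MODES = ("fc", "mirna", "deg", "coverage")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a 10-versus-10 microarray cohort: ~2000 coding genes
    and 300 lncRNAs on the (down-scaled) array, 5% differentially
    expressed at linear fold changes between 1.8x and 6x, log2 noise with
    sd 0.3, and six planted eight-gene modules. Driver lncRNAs are planted
    at |FC| >= 4.5, safely above the cascade's |FC| >= 4 bar.
    """

    n_coding: int = 2000
    n_lnc: int = 300
    n_case: int = 10
    n_control: int = 10
    frac_de: float = 0.05
    fc_range: tuple[float, float] = (1.8, 6.0)
    driver_fc_min: float = 4.5
    noise_sd: float = 0.3
    module_count: int = 6
    module_size: int = 8
    module_edge_dropout: float = 0.1
    background_edge_p: float = 0.01
    n_drivers: int = 2
    seed: int = 17

    def validate(self) -> None:
        for name in ("n_coding", "n_lnc", "n_case", "n_control",
                     "module_count", "module_size", "n_drivers"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.frac_de <= 0.5:
            raise ConfigError(f"frac_de must be in (0, 0.5], got {self.frac_de}")
        if self.fc_range[0] <= 1.5:
            raise ConfigError("fc_range lower bound must exceed 1.5")
        if self.fc_range[0] >= 4.0:
            raise ConfigError("fc_range lower bound must be below 4 so a "
                              "sub-threshold decoy lncRNA can be planted")
        if self.driver_fc_min < 4.0:
            raise ConfigError("driver_fc_min must be >= 4")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.module_edge_dropout <= 0.1:
            raise ConfigError("module_edge_dropout must be in [0, 0.1]")
        if not 0 <= self.background_edge_p <= 1:
            raise ConfigError("background_edge_p must be in [0, 1]")

    @property
    def n_de_coding(self) -> int:
        return round(self.frac_de * self.n_coding)

    @property
    def n_de_lnc(self) -> int:
        return max(round(self.frac_de * self.n_lnc),
                   self.n_drivers + len(DECOY_MODES))


@dataclass
class TruthBundle:
    """Planted ground truth recorded alongside every generated artifact."""

    de_up: frozenset[str]
    de_down: frozenset[str]
    planted_fc: dict[str, float]
    planted_modules: list[frozenset[str]]
    driver_lncs: frozenset[str]
    decoy_lncs: dict[str, str]          # lnc id -> failure mode
    planted_chains: set[tuple[str, str, str]]
    coding_features: list[str]
    lnc_features: list[str]
    seed: int

    def validate(self) -> None:
        if self.de_up & self.de_down:
            raise ConfigError("de_up and de_down overlap")
        de_coding = (self.de_up | self.de_down) & set(self.coding_features)
        for i, module in enumerate(self.planted_modules):
            if not module <= de_coding:
                raise ConfigError(f"planted module {i} not a subset of "
                                  "planted DE coding features")
        for driver in self.driver_lncs:
            reached = {
                i for i, module in enumerate(self.planted_modules)
                if any(l == driver and g in module
                       for l, _, g in self.planted_chains)
            }
            if self.planted_chains and reached != set(
                    range(len(self.planted_modules))):
                raise ConfigError(
                    f"driver {driver} lacks a chain into every module")

    def as_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "de_up": sorted(self.de_up),
            "de_down": sorted(self.de_down),
            "planted_fc": {k: self.planted_fc[k]
                           for k in sorted(self.planted_fc)},
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "driver_lncs": sorted(self.driver_lncs),
            "decoy_lncs": dict(sorted(self.decoy_lncs.items())),
            "planted_chains": sorted(map(list, self.planted_chains)),
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("truth", "matrix", "network", "regulatory", "genesets")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _gene(i: int) -> str:
    return f"GENE{i:05d}"


def _lnc(i: int) -> str:
    return f"LNC{i:04d}"


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[ExpressionMatrix, TruthBundle]:
    """Generate the expression matrix and the truth bundle.

    Baseline log2 means are uniform in [5, 12] (typical array intensity
    range; inert to the statistics). Planted DE features are shifted by
    ``sign * log2(|FC|)`` in case samples only; all cells receive i.i.d.
    Gaussian log2 noise with sd ``noise_sd``.
    """
    config.validate()
    needed = config.module_count * config.module_size
    if config.n_de_coding < needed:
        raise ConfigError(
            f"frac_de x n_coding = {config.n_de_coding} DE coding genes "
            f"cannot fill {config.module_count} modules of "
            f"{config.module_size}")
    rng = _streams(config.seed)["truth"]
    coding = [_gene(i) for i in range(config.n_coding)]
    lncs = [_lnc(i) for i in range(config.n_lnc)]

    de_coding = sorted(str(g) for g in rng.choice(
        coding, size=config.n_de_coding, replace=False))
    rng.shuffle(de_coding)
    half = len(de_coding) // 2
    planted_fc: dict[str, float] = {}
    for j, g in enumerate(de_coding):
        mag = rng.uniform(*config.fc_range)
        planted_fc[g] = mag if j < half else -mag

    module_genes = de_coding[:needed]     # already shuffled
    planted_modules = [
        frozenset(module_genes[i * config.module_size:
                               (i + 1) * config.module_size])
        for i in range(config.module_count)
    ]

    de_lnc = sorted(str(l) for l in rng.choice(
        lncs, size=config.n_de_lnc, replace=False))
    rng.shuffle(de_lnc)
    drivers = de_lnc[:config.n_drivers]
    decoys = dict(zip(de_lnc[config.n_drivers:
                             config.n_drivers + len(DECOY_MODES)],
                      DECOY_MODES))
    # The decoy taxonomy is identifiable only if planted magnitudes stay
    # on their side of the cascade's |FC| >= 4 bar after measurement
    # noise: keep a 4-standard-error guard band around the boundary on
    # the log2 scale (zero when noise_sd = 0).
    se = config.noise_sd * math.sqrt(1 / config.n_case
                                     + 1 / config.n_control)
    strong_lo = max(config.driver_fc_min, 4.0 * 2 ** (4 * se))
    strong_hi = max(config.fc_range[1], strong_lo + 0.5)
    weak_hi = min(3.9, 4.0 * 2 ** (-4 * se))
    # the sub-threshold decoy must still be a reliable DEG, so it also
    # keeps the guard band above the |FC| >= 1.5 selection boundary
    weak_lo = max(config.fc_range[0], 1.5 * 2 ** (4 * se))
    if weak_hi <= weak_lo:
        raise ConfigError(
            "noise_sd too large to plant a sub-threshold decoy lncRNA: "
            f"need {weak_lo:.2f} <= |FC| < {weak_hi:.2f}")
    for l in de_lnc:
        mode = decoys.get(l)
        if mode == "fc":
            mag = rng.uniform(weak_lo, weak_hi)
        elif l in drivers or mode in ("mirna", "deg", "coverage"):
            mag = rng.uniform(strong_lo, strong_hi)
        else:
            mag = rng.uniform(*config.fc_range)
        planted_fc[l] = mag if rng.random() < 0.5 else -mag

    de_up = frozenset(f for f, fc in planted_fc.items() if fc > 0)
    de_down = frozenset(f for f, fc in planted_fc.items() if fc < 0)
    truth = TruthBundle(
        de_up=de_up, de_down=de_down, planted_fc=planted_fc,
        planted_modules=planted_modules, driver_lncs=frozenset(drivers),
        decoy_lncs=decoys, planted_chains=set(),
        coding_features=coding, lnc_features=lncs, seed=config.seed)
    truth.validate()

    rng_m = _streams(config.seed)["matrix"]
    features = coding + lncs
    samples = ([f"case{i + 1:02d}" for i in range(config.n_case)]
               + [f"ctrl{i + 1:02d}" for i in range(config.n_control)])
    baseline = rng_m.uniform(5.0, 12.0, size=len(features))
    values = np.tile(baseline[:, None], (1, len(samples)))
    shift = np.array([
        math.copysign(math.log2(abs(planted_fc[f])), planted_fc[f])
        if f in planted_fc else 0.0
        for f in features
    ])
    values[:, :config.n_case] += shift[:, None]
    if config.noise_sd > 0:
        values = values + rng_m.normal(0.0, config.noise_sd, size=values.shape)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=samples),
        group_of={s: ("case" if s.startswith("case") else "control")
                  for s in samples},
        class_of={**{g: CODING for g in coding}, **{l: LNCRNA for l in lncs}},
    )
    return matrix, truth


def generate_network(truth: TruthBundle, config: GeneratorConfig) -> nx.Graph:
    """PPI edge list: planted near-clique modules plus sparse background.

    Each module is a clique with at most ``module_edge_dropout`` of its
    edges removed, constrained so every member keeps within-module degree
    >= 4 (hence ``module_size >= 6``). Within-module scores lie in
    [0.7, 0.99]; background edges (probability ``background_edge_p``
    among DE coding genes plus an equal-sized margin of non-DE genes)
    score in [0.4, 0.7].
    """
    if config.module_size < 6:
        raise ConfigError("module_size must be >= 6 to guarantee a 4-core "
                          "after edge dropout")
    rng = _streams(config.seed)["network"]
    graph = nx.Graph()
    module_edge_set: set[tuple[str, str]] = set()
    for module in truth.planted_modules:
        members = sorted(module)
        edges = [(a, b) for i, a in enumerate(members)
                 for b in members[i + 1:]]
        degree = {m: len(members) - 1 for m in members}
        order = rng.permutation(len(edges))
        target = math.floor(config.module_edge_dropout * len(edges))
        dropped = 0
        keep = set(range(len(edges)))
        for idx in order:
            if dropped >= target:
                break
            a, b = edges[idx]
            if degree[a] > 4 and degree[b] > 4:
                keep.discard(idx)
                degree[a] -= 1
                degree[b] -= 1
                dropped += 1
        for idx in sorted(keep):
            a, b = edges[idx]
            graph.add_edge(a, b, score=float(rng.uniform(0.7, 0.99)))
            module_edge_set.add((a, b))

    de_coding = sorted((truth.de_up | truth.de_down)
                       & set(truth.coding_features))
    non_de = [g for g in truth.coding_features
              if g not in truth.de_up and g not in truth.de_down]
    margin = non_de[:len(de_coding)]
    candidates = sorted(de_coding + margin)
    if config.background_edge_p > 0:
        pairs = [(a, b) for i, a in enumerate(candidates)
                 for b in candidates[i + 1:]
                 if (a, b) not in module_edge_set]
        mask = rng.random(len(pairs)) < config.background_edge_p
        for (a, b), hit in zip(pairs, mask):
            if hit:
                graph.add_edge(a, b, score=float(rng.uniform(0.4, 0.7)))
    return graph


def generate_regulatory(truth: TruthBundle, config: GeneratorConfig
                        ) -> RegulatoryAnnotation:
    """Plant lncRNA->miRNA->gene chains and the decoy annotation.

    For every driver (and the ``fc`` decoy, which must fail only the
    fold-change bar) one miRNA per module targets ~60% of that module's
    genes plus one non-module DEG; drivers also get two direct
    lncRNA->gene targets. The ``coverage`` decoy gets the same treatment
    for a strict subset of the modules; the ``deg`` decoy's miRNAs target only
    non-DE genes; the ``mirna`` decoy gets direct targets but no miRNA.
    All planted (lncRNA, miRNA, gene) triples are recorded in
    ``truth.planted_chains``.
    """
    if not truth.planted_modules:
        raise ConfigError("cannot plant regulatory chains with zero modules")
    rng = _streams(config.seed)["regulatory"]
    lnc_mirna: set[tuple[str, str]] = set()
    lnc_gene: set[tuple[str, str]] = set()
    mirna_gene: set[tuple[str, str]] = set()
    chains: set[tuple[str, str, str]] = set()

    de_coding = sorted((truth.de_up | truth.de_down)
                       & set(truth.coding_features))
    module_genes = set().union(*truth.planted_modules)
    non_module_de = [g for g in de_coding if g not in module_genes]
    non_de = [g for g in truth.coding_features
              if g not in truth.de_up and g not in truth.de_down]
    counter = 0

    def next_mirna() -> str:
        nonlocal counter
        counter += 1
        return f"miR-{counter:03d}"

    def plant_chains(lnc: str, modules: list[frozenset[str]]) -> None:
        per_module = max(1, round(0.6 * config.module_size))
        for module in modules:
            mirna = next_mirna()
            lnc_mirna.add((lnc, mirna))
            genes = sorted(str(g) for g in rng.choice(
                sorted(module), size=per_module, replace=False))
            if non_module_de:
                genes.append(non_module_de[
                    int(rng.integers(len(non_module_de)))])
            for g in genes:
                mirna_gene.add((mirna, g))
                chains.add((lnc, mirna, g))

    modes_to_lnc = {mode: l for l, mode in truth.decoy_lncs.items()}
    for driver in sorted(truth.driver_lncs):
        plant_chains(driver, truth.planted_modules)
        for g in rng.choice(de_coding, size=2, replace=False):
            lnc_gene.add((str(driver), str(g)))
    if "fc" in modes_to_lnc:
        plant_chains(modes_to_lnc["fc"], truth.planted_modules)
    if "coverage" in modes_to_lnc and len(truth.planted_modules) >= 2:
        # strict module subset; leave two modules unreached (where the
        # geometry allows) so a single spurious module merger downstream
        # cannot hand the decoy full coverage by accident
        n_cov = max(1, len(truth.planted_modules) - 2)
        plant_chains(modes_to_lnc["coverage"],
                     truth.planted_modules[:n_cov])
    if "mirna" in modes_to_lnc:
        lnc = modes_to_lnc["mirna"]
        for module in truth.planted_modules:
            g = sorted(module)[int(rng.integers(len(module)))]
            lnc_gene.add((lnc, g))
    if "deg" in modes_to_lnc:
        lnc = modes_to_lnc["deg"]
        for _ in range(2):
            mirna = next_mirna()
            lnc_mirna.add((lnc, mirna))
            for g in rng.choice(non_de, size=4, replace=False):
                mirna_gene.add((mirna, str(g)))

    # background annotation noise: miRNAs unrelated to any planted lncRNA
    for _ in range(3):
        mirna = next_mirna()
        for g in rng.choice(non_de, size=3, replace=False):
            mirna_gene.add((mirna, str(g)))

    truth.planted_chains = chains
    truth.validate()
    return RegulatoryAnnotation(
        lnc_to_mirna=frozenset(lnc_mirna),
        lnc_to_gene=frozenset(lnc_gene),
        mirna_to_gene=frozenset(mirna_gene))


def generate_genesets(truth: TruthBundle, config: GeneratorConfig
                      ) -> GeneSetCollection:
    """One gene set per planted module (padded with random genes) plus
    random decoy sets; universe = all coding features."""
    rng = _streams(config.seed)["genesets"]
    sets: dict[str, frozenset[str]] = {}
    pool = truth.coding_features
    for i, module in enumerate(truth.planted_modules, start=1):
        extra = {str(g) for g in rng.choice(pool, size=5, replace=False)}
        sets[f"PLANTED_MODULE_{i}"] = frozenset(module | extra)
    for j in range(1, 5):
        sets[f"RANDOM_SET_{j}"] = frozenset(
            str(g) for g in rng.choice(pool, size=30, replace=False))
    return GeneSetCollection(sets=sets, universe=frozenset(pool))


@dataclass
class SyntheticBundle:
    """Everything one generated study comprises."""

    config: GeneratorConfig
    matrix: ExpressionMatrix
    network: nx.Graph
    annotation: RegulatoryAnnotation
    genesets: GeneSetCollection
    truth: TruthBundle


def generate_all(config: GeneratorConfig) -> SyntheticBundle:
    """Generate every pipeline input for one seeded study."""
    matrix, truth = generate_cohort(config)
    network = generate_network(truth, config)
    annotation = generate_regulatory(truth, config)
    genesets = generate_genesets(truth, config)
    return SyntheticBundle(config=config, matrix=matrix, network=network,
                           annotation=annotation, genesets=genesets,
                           truth=truth)


FIXTURE_FILES = {
    "matrix": "expression.tsv",
    "groups": "groups.tsv",
    "classes": "classes.tsv",
    "edges": "edges.tsv",
    "lnc_mirna": "lnc_mirna.tsv",
    "lnc_gene": "lnc_gene.tsv",
    "mirna_gene": "mirna_gene.tsv",
    "gmt": "gene_sets.gmt",
    "truth": "truth.json",
}


def write_fixture(directory: str | Path, bundle: SyntheticBundle,
                  force: bool = False) -> dict:
    """Write every input file plus truth.json and manifest.json.

    Refuses a non-empty target directory unless ``force`` is set.
    Returns the manifest (relative paths, seed, config).
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ConfigError(f"refusing to write into non-empty {directory} "
                          "(pass force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    f = FIXTURE_FILES
    io_formats.write_expression(bundle.matrix, directory / f["matrix"],
                                directory / f["groups"],
                                directory / f["classes"])
    io_formats.write_edge_list(bundle.network, directory / f["edges"])
    io_formats.write_pairs(set(bundle.annotation.lnc_to_mirna),
                           directory / f["lnc_mirna"], ("lncRNA", "miRNA"))
    io_formats.write_pairs(set(bundle.annotation.lnc_to_gene),
                           directory / f["lnc_gene"], ("lncRNA", "gene"))
    io_formats.write_pairs(set(bundle.annotation.mirna_to_gene),
                           directory / f["mirna_gene"], ("miRNA", "gene"))
    io_formats.write_gmt(bundle.genesets, directory / f["gmt"])
    (directory / f["truth"]).write_text(
        json.dumps(bundle.truth.as_json_dict(), indent=1, sort_keys=True)
        + "\n")
    manifest = {
        "seed": bundle.config.seed,
        "config": dataclasses.asdict(bundle.config),
        "files": dict(sorted(f.items())),
        "checksums": {
            name: hashlib.sha256((directory / fname).read_bytes()).hexdigest()
            for name, fname in sorted(f.items())
        },
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
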