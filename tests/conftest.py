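"""Shared fixtures: small protocol objects and session-scoped simulations.

The heavier simulated systems (benchmark conditions: 200 genes x 1 kb, two
haploid parents at 5% divergence, 50x per-homeolog coverage, 1% sequencing
error) are session-scoped so the acceptance tests share one run.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

import homeoseq as hs


@pytest.fixture()
def two_parent_protocol() -> hs.ProtocolTable:
    """Minimal haploid two-parent protocol (paths are placeholders)."""
    return hs.ProtocolTable(
        (
            hs.SampleSpec("P1_mRNA_1", "parent1", "mRNA", 1, "p1.sam", "sam"),
            hs.SampleSpec("P2_mRNA_1", "parent2", "mRNA", 1, "p2.sam", "sam"),
            hs.SampleSpec("child_mRNA_1", "child", "mRNA", 1, "c.sam", "sam"),
        ),
        {1: 1, 2: 1},
    )


class RunResult:
    """A simulated system plus the tables its pipeline run produced."""

    def __init__(self, system: hs.simdata.SimulatedSystem, paths: dict[str, Path]):
        self.system = system
        self.truth = system.truth
        self.paths = paths
        self.expression = pd.read_csv(paths["expression"], sep="\t")
        self.snp = pd.read_csv(paths["snp"], sep="\t")
        self.read = pd.read_csv(paths["read"], sep="\t")
        self.summary = pd.read_csv(paths["summary"], sep="\t")
        self.chimera = (
            pd.read_csv(paths["chimera"], sep="\t") if "chimera" in paths else None
        )

    def metrics(self) -> dict[str, float]:
        return hs.evaluate(self.truth, self.read, self.snp, self.chimera)


def simulate_and_run(
    params: hs.SimParams, workdir: Path, config: hs.RunConfig | None = None
) -> RunResult:
    system = hs.simulate_system(params, workdir / "sim")
    protocol = hs.parse_protocol(system.protocol_path)
    reference = hs.read_reference(system.reference_path)
    paths = hs.run(
        protocol, reference, workdir / "out", "run",
        config=config or hs.RunConfig(chimera=True),
    )
    return RunResult(system, paths)


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory) -> RunResult:
    """Benchmark conditions: 200 genes x 1 kb, d=5%, 50x/homeolog, 1% error,
    novel substitutions planted at rate 0.002, no chimeric genes."""
    params = hs.SimParams(seed=20200, novel_rate=0.002)
    return simulate_and_run(params, tmp_path_factory.mktemp("benchmark"))


@pytest.fixture(scope="session")
def chimeric_run(tmp_path_factory) -> RunResult:
    """20 genes, all chimeric, at the benchmark coverage and error rate."""
    params = hs.SimParams(seed=20201, n_genes=20, chimeric_fraction=1.0)
    return simulate_and_run(params, tmp_path_factory.mktemp("chimeric"))


@pytest.fixture(scope="session")
def low_coverage_run(tmp_path_factory) -> RunResult:
    """Sparse regime: ~15 reads per gene in every sample, 6% divergence."""
    params = hs.SimParams(
        seed=20202,
        n_genes=200,
        divergence=0.06,
        coverage=0.75,  # 2 homeologs x 0.75x -> ~15 child reads/gene
        parent_coverage=1.5,  # ~15 parent reads/gene
    )
    return simulate_and_run(params, tmp_path_factory.mktemp("lowcov"))
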