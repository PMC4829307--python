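"""Shared fixtures: toy gene models and seeded synthetic studies.

All sequencing-like inputs are generated at test time by the synthetic
module; nothing binary is stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from splicestep.gene_model import ExonInterval, GeneModel
from splicestep.synthetic import (
    PlantedEvent,
    SimulationConfig,
    emit_read_pairs,
    simulate_gene,
    simulate_sample,
    simulate_transcripts,
)


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    """3 exons on +: 1-100, 201-300, 1001-1100; introns 101-200 and 301-1000."""
    return GeneModel(
        gene_id="TOY",
        chrom="chrT",
        strand="+",
        exons=[ExonInterval(1, 1, 100), ExonInterval(2, 201, 300), ExonInterval(3, 1001, 1100)],
    )


@pytest.fixture(scope="session")
def minus_model() -> GeneModel:
    """Same intervals on -: transcript order runs high -> low coordinates."""
    return GeneModel(
        gene_id="TOYM",
        chrom="chrT",
        strand="-",
        exons=[ExonInterval(1, 1001, 1100), ExonInterval(2, 201, 300), ExonInterval(3, 1, 100)],
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """5-intron simulation with a SAM on disk and per-pair truth labels."""
    cfg = SimulationConfig(n_introns=5, depth=60, n_molecules=600, seed=11)
    rng = np.random.default_rng(cfg.seed)
    model, seq = simulate_gene(cfg, rng)
    molecules = simulate_transcripts(model, cfg, rng)
    sam, truth = emit_read_pairs(molecules, model, cfg, rng)
    path = tmp_path_factory.mktemp("smallsim") / "reads.sam"
    path.write_text(sam)
    return {"cfg": cfg, "model": model, "seq": seq, "sam": str(path),
            "truth": truth, "molecules": molecules}


ORDER_RATES = [0.03 if n % 2 == 1 else 0.9 for n in range(1, 21)]


@pytest.fixture(scope="session")
def order_study(tmp_path_factory):
    """20 introns, the 10 odd ones planted non-sequential (removal 10x+
    slower than their downstream neighbor), sequenced to ~300x."""
    cfg = SimulationConfig(
        n_introns=20,
        intron_length_range=(600, 2000),
        removal_rates=ORDER_RATES,
        depth=300,
        n_molecules=3000,
        seed=3,
    )
    rng = np.random.default_rng(cfg.seed)
    model, seq = simulate_gene(cfg, rng)
    molecules = simulate_transcripts(model, cfg, rng)
    sam, truth = emit_read_pairs(molecules, model, cfg, rng)
    path = tmp_path_factory.mktemp("ordersim") / "reads.sam"
    path.write_text(sam)
    return {"cfg": cfg, "model": model, "sam": str(path), "truth": truth}


EVENT_PLAN = (
    PlantedEvent(2, "5RS", (600,)),
    PlantedEvent(4, "3RS", (1200,)),
    PlantedEvent(6, "nested", (400, 900)),
    PlantedEvent(8, "intermezzo", (500, 900)),
    # planted in only 2 of the 3 cell lines: must never survive intersection
    PlantedEvent(9, "nested", (700, 1100), cell_lines=("A", "B")),
)


@pytest.fixture(scope="session")
def event_study(tmp_path_factory):
    """3 cell lines with planted multi-step events (one leaking 2-of-3)."""
    cfg = SimulationConfig(
        n_introns=10,
        intron_length_range=(2000, 4000),
        removal_rates=0.3,
        planted_events=EVENT_PLAN,
        depth=150,
        n_molecules=1500,
        seed=5,
    )
    rng = np.random.default_rng(cfg.seed)
    model, seq = simulate_gene(cfg, rng)
    root = tmp_path_factory.mktemp("eventsim")
    sams = {}
    for i, line in enumerate(("A", "B", "C")):
        sam, _ = simulate_sample(model, cfg, f"lib{i}", line, seed=100 + i)
        p = root / f"{line}.sam"
        p.write_text(sam)
        sams[line] = str(p)
    return {"cfg": cfg, "model": model, "seq": seq, "sams": sams}
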