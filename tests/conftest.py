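import pytest

from meninscope.simulate import (
    InteractomeSpec,
    LandscapeSpec,
    StructureSpec,
    make_toy_structure,
    simulate_interactome,
    simulate_peak_landscape,
)
from meninscope.structure.interface import InterfaceDefinition
from meninscope.structure.model import read_structure


@pytest.fixture(scope="session")
def toy_structure():
    """Toy chain with a planted clash (pos 3), H-bond Ser (pos 7) and an
    interface contact (pos 11)."""
    spec = StructureSpec(
        n_residues=14,
        clash_positions=(3,),
        hbond_positions=(7,),
        interface_positions=(11,),
    )
    pdb_text, truth = make_toy_structure(spec, seed=1)
    model = read_structure(pdb_text, source_id="toy")
    idef = InterfaceDefinition(
        "partner", "toy", (spec.chain_id,), (spec.partner_chain_id,), radius=5.0
    )
    return {"spec": spec, "pdb": pdb_text, "truth": truth, "model": model,
            "interface": idef}


@pytest.fixture(scope="session")
def interactome():
    spec = InteractomeSpec(
        interactors={"KMT2A": 0.5, "WDR5": 1.0, "JUND": 0.1},
    )
    table, design, truth = simulate_interactome(spec, seed=42)
    return {"spec": spec, "table": table, "design": design, "truth": truth}


@pytest.fixture(scope="session")
def landscape():
    spec = LandscapeSpec(
        mutant_loss={
            "R52G": [("c4", 0.3, 0.05), ("c5", 0.5, 0.05)],
            "E408Q": [],
        },
        spike_reads={"WT": (1_000_000, 10_000), "R52G": (2_000_000, 10_000)},
    )
    return {"spec": spec, "data": simulate_peak_landscape(spec, seed=11)}
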