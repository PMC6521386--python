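import numpy as np
import pandas as pd
import pytest

from bileflux.builder import DietSpec, build_strain_model
from bileflux.pathway import ENZYME_CLASSES, StrainGenotype


@pytest.fixture(scope="session")
def diet():
    return DietSpec.default()


@pytest.fixture(scope="session")
def scenario_genotypes():
    """Strains covering the 3alpha/3beta-HSDH carrier combinations."""
    return {
        "bsh1": StrainGenotype("bsh1", {"BSH"}),
        "bsh2": StrainGenotype("bsh2", {"BSH"}),
        "alpha1": StrainGenotype("alpha1", {"HSDH_3A"}),
        "alpha2": StrainGenotype("alpha2", {"HSDH_3A"}),
        "beta1": StrainGenotype("beta1", {"HSDH_3B"}),
        "dual1": StrainGenotype("dual1", {"HSDH_3A", "HSDH_3B"}),
        "plain": StrainGenotype("plain", set()),
        "h12": StrainGenotype("h12", {"HSDH_12A"}),
        "h7": StrainGenotype("h7", {"HSDH_7A"}),
    }


def random_genotype(rng: np.random.Generator, strain_id: str,
                    p: float = 0.35, exclude: tuple[str, ...] = ("CHOL_RED",)
                    ) -> StrainGenotype:
    """Random enzyme subset; each class present with probability p."""
    enzymes = {e for e in ENZYME_CLASSES if e not in exclude and rng.random() < p}
    return StrainGenotype(strain_id, enzymes)


def single_model(genotype, diet):
    from bileflux.builder import apply_diet

    return apply_diet(build_strain_model(genotype), diet)
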