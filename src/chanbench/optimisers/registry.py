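"""The approach registry: optimiser + modification pairings from the
ion-channel fitting literature.

Each approach is named by first author's surname and year (with an a-z
suffix where one publication described several), and couples an optimiser
with the binary modification settings extracted from the original
description.  The registry holds 42 approaches from 30 publications; eight
are duplicates of an earlier identical optimiser+modification pairing and
carry a ``duplicate_of`` pointer.  Optimisers span six categories:
Gradient Descent, Simplex, Genetic Algorithms, PSO, Hybrid and Other.
A core set of optimisers is implemented (see
:data:`IMPLEMENTED_OPTIMISERS`); the remaining entries are registry
placeholders whose runners raise ``NotImplementedError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from chanbench.modifications import Modification

__all__ = ["ApproachSpec", "approach_registry", "get_approach", "IMPLEMENTED_OPTIMISERS"]


@dataclass(frozen=True)
class ApproachSpec:
    name: str
    citation: str       # source-publication key; 30 distinct across the registry
    optimiser: str
    category: str       # GD | Simplex | GA | PSO | Hybrid | Other
    uses_gradient: bool
    modification: Modification
    duplicate_of: str | None = None


# Optimiser ids with working runners.  Hybrid combinators (a+b sequential,
# a/b interleaved) are composed from the base set.
IMPLEMENTED_OPTIMISERS = frozenset({
    "trr", "lm", "nelder_mead", "powell", "conjugate_gd", "sqp",
    "cma_es", "pso", "ga", "pattern_search",
    "pso+trr", "pso/trr", "pso/trr+trr", "pso+nm", "pso/nm",
})


def _mod(log=False, scale=False, pbounds=False, rbounds=False):
    return Modification(log_transform=log, scale_transform=scale,
                        parameter_bounds=pbounds, rate_bounds=rbounds)


# name, citation, optimiser, category, gradient, (log, scale, pbounds, rbounds), duplicate_of
_ROWS = [
    ("Balser1990a", "Balser1990", "lm", "GD", True, (0, 0, 0, 0), None),
    ("Balser1990b", "Balser1990", "nelder_mead", "Simplex", False, (0, 0, 0, 0), None),
    ("Maryak1998", "Maryak1998", "spsa", "GD", True, (0, 0, 0, 0), None),
    ("Clancy1999", "Clancy1999", "lm", "GD", True, (0, 0, 0, 0), "Balser1990a"),
    ("Vanier1999a", "Vanier1999", "conjugate_gd", "GD", True, (0, 1, 1, 0), None),
    ("Vanier1999b", "Vanier1999", "simulated_annealing", "Other", False, (0, 1, 1, 0), None),
    ("Vanier1999c", "Vanier1999", "stochastic_search", "Other", False, (0, 1, 1, 0), None),
    ("Vanier1999d", "Vanier1999", "random_search", "Other", False, (0, 1, 1, 0), None),
    ("Sachse2003a", "Sachse2003", "conjugate_gd", "GD", True, (0, 0, 0, 0), None),
    ("Sachse2003b", "Sachse2003", "powell", "GD", True, (0, 0, 0, 0), None),
    ("Dokos2004", "Dokos2004", "curvilinear_gd", "GD", True, (0, 0, 1, 0), None),
    ("Gurkiewicz2007a", "Gurkiewicz2007", "ga", "GA", False, (0, 0, 1, 0), None),
    ("Gurkiewicz2007b", "Gurkiewicz2007", "ga", "GA", False, (0, 0, 1, 0), None),
    ("Bueno-Orovio2008", "BuenoOrovio2008", "sqp", "GD", True, (0, 0, 1, 0), None),
    ("Seemann2009a", "Seemann2009", "pso", "PSO", False, (0, 0, 0, 0), None),
    ("Seemann2009b", "Seemann2009", "powell", "GD", True, (0, 0, 0, 0), "Sachse2003b"),
    ("Zhou2009", "Zhou2009", "de/lm", "Hybrid", True, (0, 0, 0, 0), None),
    ("Guo2010", "Guo2010", "curvilinear_gd", "GD", True, (0, 0, 1, 0), "Dokos2004"),
    ("Liu2011", "Liu2011", "pso/nm", "Hybrid", False, (0, 0, 1, 0), None),
    ("Ben-Shalom2012", "BenShalom2012", "ga", "GA", False, (0, 0, 1, 0), None),
    ("Bot2012", "Bot2012", "ga", "GA", False, (0, 1, 1, 0), None),
    ("Chen2012", "Chen2012", "pso", "PSO", False, (0, 0, 1, 0), None),
    ("Davies2012", "Davies2012", "nelder_mead", "Simplex", False, (0, 1, 1, 0), None),
    ("Wilhelms2012a", "Wilhelms2012", "powell", "GD", True, (0, 0, 0, 0), "Sachse2003b"),
    ("Wilhelms2012b", "Wilhelms2012", "trr", "GD", True, (0, 0, 1, 0), None),
    ("Abed2013", "Abed2013", "curvilinear_gd", "GD", True, (0, 0, 1, 0), "Dokos2004"),
    ("Du2014", "Du2014", "trr", "GD", True, (0, 0, 1, 0), "Wilhelms2012b"),
    ("Groenendaal2015", "Groenendaal2015", "ga", "GA", False, (0, 1, 1, 0), None),
    ("Loewe2016a", "Loewe2016", "trr", "GD", True, (0, 0, 1, 0), "Wilhelms2012b"),
    ("Loewe2016b", "Loewe2016", "pso", "PSO", False, (0, 0, 1, 0), None),
    ("Loewe2016c", "Loewe2016", "pso+trr", "Hybrid", True, (0, 0, 1, 0), None),
    ("Loewe2016d", "Loewe2016", "pso/trr", "Hybrid", True, (0, 0, 1, 0), None),
    ("Loewe2016e", "Loewe2016", "pso/trr+trr", "Hybrid", True, (0, 0, 1, 0), None),
    ("Moreno2016", "Moreno2016", "nelder_mead", "Simplex", False, (0, 0, 1, 0), None),
    ("Cairns2017", "Cairns2017", "ga", "GA", False, (0, 0, 1, 0), None),
    ("Jedrzejewski-Szmek2018", "JedrzejewskiSzmek2018", "cma_es", "Other", False, (0, 0, 1, 0), None),
    ("Beattie2018", "Beattie2018", "cma_es", "Other", False, (1, 0, 1, 1), None),
    ("Clerx2019", "Clerx2019", "cma_es", "Other", False, (1, 0, 1, 1), "Beattie2018"),
    ("Clausen2020", "Clausen2020", "pso+nm", "Hybrid", False, (0, 0, 1, 0), None),
    ("Smirnov2020", "Smirnov2020", "ga", "GA", False, (0, 1, 1, 0), None),
    ("Cabo2022", "Cabo2022", "pso", "PSO", False, (0, 0, 1, 0), None),
    ("Kohjitani2022", "Kohjitani2022", "pattern_search", "Other", False, (0, 1, 0, 0), None),
]


def approach_registry() -> list[ApproachSpec]:
    """All 42 registered approaches (30 distinct source publications)."""
    specs = []
    for name, cite, opt, cat, grad, flags, dup in _ROWS:
        specs.append(ApproachSpec(
            name=name, citation=cite, optimiser=opt, category=cat,
            uses_gradient=bool(grad),
            modification=_mod(*(bool(f) for f in flags)),
            duplicate_of=dup,
        ))
    return specs


def get_approach(name: str) -> ApproachSpec:
    for spec in approach_registry():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown approach {name!r}")
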