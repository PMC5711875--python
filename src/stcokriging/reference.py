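"""A published reference model set for urban topsoil heavy metals.

Fitted sum-metric models for four heavy metals surveyed annually over five
years in an industrial urban district: Cu, Cd and Pb on a base-2 log scale
(LogCu, LogCd, LogPb) and Zn on its raw scale (mg/kg). All ten pair models
share the single anisotropy ratio alpha = 2085 m^2/yr^2. Temporal parts are
linear; spatial and spatiotemporal parts are spherical except the
LogCu x LogPb pair (gaussian) and the LogCu x Zn pair (exponential).

This set is useful as a realistic worked example and as a stress case for
:func:`stcokriging.models.validity_report`: like many independently fitted
pair models, it is *not* a valid coregionalization (e.g. the LogCd x Zn
spatiotemporal sill violates the Cauchy-Schwarz bound), so kriging with it
can produce negative variances, which the predictor floors at zero.
"""

from __future__ import annotations

from .models import BilonickModel, ModelSet, SharedAnisotropy

SOIL_METALS_ALPHA = 2085.0

_ROWS = [
    # var_u, var_v, C0, CT, CS, aS, CST, aST, s_kind, st_kind
    ("LogCu", "LogCu", 0.17, 0.009, 0.175, 5375, 0.225, 734, "spherical", "spherical"),
    ("LogCd", "LogCd", 0.033, 0.0035, 0.103, 5843, 0.1247, 18, "spherical", "spherical"),
    ("LogPb", "LogPb", 0.54, 0.032, 0.34, 5023, 0.46, 4218, "spherical", "spherical"),
    ("Zn", "Zn", 503, 12.12, 2967, 4457, 564, 101, "spherical", "spherical"),
    ("LogCd", "LogCu", 0.131, 0.006, 0.237, 4242, 0.031, 4812, "spherical", "spherical"),
    ("LogCd", "LogPb", 0.05, 0.0082, 0.119, 3660, 0.187, 2159, "spherical", "spherical"),
    ("LogCd", "Zn", 0.31, 0.12, 4.375, 4060, 12.07, 4259, "spherical", "spherical"),
    ("LogCu", "LogPb", 0.097, 0.011, 0.212, 2898, 0.202, 5847, "gaussian", "gaussian"),
    ("LogCu", "Zn", 2.03, 0.263, 16.48, 3203, 9.22, 6265, "exponential", "exponential"),
    ("LogPb", "Zn", 4.53, 0.32, 5.97, 5722, 2.75, 2511, "spherical", "spherical"),
]


def soil_metals_model_set() -> ModelSet:
    """The ten-pair reference ModelSet (4 auto + 6 cross models)."""
    models = [
        BilonickModel(u, v, float(c0), float(ct), float(cs), float(a_s), float(cst), float(a_st), sk, stk)
        for u, v, c0, ct, cs, a_s, cst, a_st, sk, stk in _ROWS
    ]
    return ModelSet.from_models(models, SharedAnisotropy(SOIL_METALS_ALPHA))
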