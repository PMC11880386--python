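"""Published summary statistics of the reference NSCLC anti-PD1 cohort.

The clinical analytics in this package were designed around a retrospective
phase III NSCLC cohort (n = 129) receiving anti-PD1 combination therapy, in
which baseline tumor volume (BTV) was measured from contrast-enhanced CT
and PD-L1 expression as the tumor proportion score (TPS). Its published
marginal counts, operating characteristics, and logistic coefficients are
collected here; together they fully determine the response x TPS x BTV
contingency tables, which :func:`hiskit.cohort.reconstruct_tps_table` and
:func:`hiskit.cohort.reconstruct_joint_table` rebuild.

Conventions
-----------
* ``BTV_CUTOFF`` is the Youden-optimal BTV threshold reported for the
  cohort (scanner volume units). It cannot be recomputed without the
  patient images; it ships as a documented constant.
* In the logistic models, the BTV indicator is 1 for BTV *below* the
  cutoff (BTV-small) and the TPS indicator is 1 for TPS >= the cut.
  Small tumors respond more often, hence the positive BTV coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

from hiskit.cohort import LogisticModel

__all__ = [
    "BTV_CUTOFF",
    "TPS_CUTS",
    "CohortMargins",
    "TABLE1_MARGINS",
    "UNIVARIATE_SENS_SPEC",
    "COMBINED_SENS_SPEC",
    "REFERENCE_MODELS",
]

#: Youden-optimal baseline-tumor-volume cutoff of the reference cohort.
BTV_CUTOFF = 10575.21

#: TPS percent cutoffs analyzed in the reference cohort.
TPS_CUTS = (25, 50, 75)


@dataclass(frozen=True)
class CohortMargins:
    """Marginal counts of a response x TPS x tumor-size cohort table.

    ``tps_pos_by_size`` maps a TPS cut (percent) to the (small, large)
    counts of TPS-positive patients in each BTV stratum.
    """

    n_small: int
    n_large: int
    resp_small: int
    nonresp_small: int
    resp_large: int
    nonresp_large: int
    tps_pos_by_size: dict[int, tuple[int, int]]

    @property
    def n_total(self) -> int:
        return self.n_small + self.n_large

    @property
    def n_resp(self) -> int:
        return self.resp_small + self.resp_large

    @property
    def n_nonresp(self) -> int:
        return self.nonresp_small + self.nonresp_large

    def tps_positive_total(self, cut: int) -> int:
        s, l = self.tps_pos_by_size[cut]
        return s + l

    def validate(self) -> None:
        if self.resp_small + self.nonresp_small != self.n_small:
            raise ValueError("small-stratum response counts do not sum to n_small")
        if self.resp_large + self.nonresp_large != self.n_large:
            raise ValueError("large-stratum response counts do not sum to n_large")
        for cut, (s, l) in self.tps_pos_by_size.items():
            if not (0 <= s <= self.n_small and 0 <= l <= self.n_large):
                raise ValueError(f"TPS>={cut} positive counts exceed stratum sizes")


#: Baseline characteristics of the reference cohort: 37 BTV-small and 92
#: BTV-large patients; 77 responders / 52 non-responders overall; TPS-
#: positive counts per stratum at cuts 25/50/75.
TABLE1_MARGINS = CohortMargins(
    n_small=37,
    n_large=92,
    resp_small=26,
    nonresp_small=11,
    resp_large=51,
    nonresp_large=41,
    tps_pos_by_size={25: (15, 48), 50: (9, 41), 75: (4, 30)},
)
TABLE1_MARGINS.validate()

#: Published (sensitivity %, specificity %) of the TPS indicator alone.
UNIVARIATE_SENS_SPEC: dict[int, tuple[float, float]] = {
    25: (64.9, 75.0),
    50: (55.8, 86.5),
    75: (39.0, 92.3),
}

#: Published (sensitivity %, specificity %) of the bivariate BTV+TPS model.
COMBINED_SENS_SPEC: dict[int, tuple[float, float]] = {
    25: (83.1, 59.6),
    50: (77.9, 65.4),
    75: (67.5, 71.2),
}


#: Published logistic equations logit = intercept + coef_btv*[BTV small]
#: + coef_tps*[TPS >= cut], one per TPS cut.
REFERENCE_MODELS: dict[int, "LogisticModel"] = {
    25: LogisticModel(intercept=-0.7155, coef_btv=0.9993, coef_tps=1.876, tps_cut=25),
    50: LogisticModel(intercept=-0.7347, coef_btv=1.241, coef_tps=2.398, tps_cut=50),
    75: LogisticModel(intercept=-0.4042, coef_btv=1.122, coef_tps=2.329, tps_cut=75),
}
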