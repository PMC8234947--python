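"""Small built-in fixtures.

* :func:`synthetic_variant_panel` — a 26-variant PCOS-style susceptibility
  panel with the three-pathway gene structure (adiposity 4, insulin-resistant
  10, reproductive 12) and two declared LD proxies.  Apart from the two real
  proxy pairs (rs10993397→rs7865239, rs8043701→rs11075468) the rsIDs are
  synthetic placeholders: this is a stand-in panel for demonstrations and
  tests, not a curated variant list.
* :func:`reported_mr_estimates` — published two-sample MR estimates of
  PCOS-related exposures on PCOS and of PCOS on disease outcomes (beta, SE
  and the printed OR with 95% CI), used to validate the beta/SE → OR/CI
  reporting arithmetic against an external reporting surface.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .sumstats import VariantPanelEntry

__all__ = ["synthetic_variant_panel", "reported_mr_estimates"]

# gene labels per planted pathway; sizes 4 / 10 / 12
_PANEL_GENES = {
    "adiposity": ["DENND1A", "DENND1A", "DENND1A", "FSHR"],
    "insulin_resistant": [
        "THADA",
        "THADA",
        "LHCGR",
        "FSHB",
        "FSHR",
        "ERBB3",
        "TOX3",
        "GATA4",
        "HMGA2",
        "KRR1",
    ],
    "reproductive": [
        "ERBB4",
        "RAB5B",
        "IRF1",
        "SOD2",
        "YAP1",
        "SUMO1B",
        "ZBTB16",
        "C9orf3",
        "C9orf3",
        "INSR",
        "THADA",
        "TOX3",
    ],
}

# (panel id, proxy id, r2): the two real proxy pairs; C9orf3's rs10993397 is
# replaced by rs7865239 and TOX3's rs8043701 by rs11075468.
_PROXIES = {
    "rs10993397": ("rs7865239", 0.9),
    "rs8043701": ("rs11075468", 0.9),
}

_ALLELE_CYCLE = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T"), ("A", "C"), ("T", "G")]


def synthetic_variant_panel() -> list[VariantPanelEntry]:
    """26-entry panel fixture; see module docstring for provenance."""
    entries: list[VariantPanelEntry] = []
    i = 0
    for pathway in ("adiposity", "insulin_resistant", "reproductive"):
        for gene in _PANEL_GENES[pathway]:
            if gene == "C9orf3" and "rs10993397" not in {e.variant_id for e in entries}:
                vid = "rs10993397"
            elif gene == "TOX3" and pathway == "insulin_resistant":
                vid = "rs8043701"
            else:
                vid = f"rs77{10000 + i}"
            risk, alt = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
            proxy = _PROXIES.get(vid)
            entries.append(
                VariantPanelEntry(
                    variant_id=vid,
                    risk_allele=risk,
                    alt_allele=alt,
                    gene_label=gene,
                    proxy_id=proxy[0] if proxy else None,
                    proxy_r2=proxy[1] if proxy else None,
                    proxy_risk_allele=risk if proxy else None,
                    proxy_alt_allele=alt if proxy else None,
                )
            )
            i += 1
    return entries


# Published MR reporting surface: trait/outcome, method, nSNV, beta, SE,
# printed OR and 95% CI bounds, p-value.
_REPORTED = """\
trait	method	n_snv	beta	se	or	or_ci_low	or_ci_high	pval
SHBG	egger	171	-0.0140	0.0067	0.986	0.973	0.999	3.926e-2
SHBG	weighted_median	171	-0.0162	0.0052	0.984	0.974	0.994	1.785e-3
SHBG	ivw	171	-0.0120	0.0035	0.988	0.981	0.995	6.694e-4
BMI_female	egger	35	1.2206	0.3224	3.389	1.802	6.376	6.157e-4
BMI_female	weighted_median	35	0.9210	0.1887	2.512	1.735	3.636	1.056e-6
BMI_female	ivw	35	0.8842	0.1209	2.421	1.910	3.068	2.611e-13
Insulin_resistance	egger	51	0.5460	0.4531	1.726	0.710	4.196	2.340e-1
Insulin_resistance	weighted_median	51	0.1011	0.2687	1.106	0.653	1.873	7.067e-1
Insulin_resistance	ivw	51	0.5267	0.2220	1.693	1.096	2.616	1.768e-2
WC_female	egger	18	0.9313	0.7627	2.538	0.569	11.316	2.398e-1
WC_female	weighted_median	18	0.6591	0.2646	1.933	1.151	3.247	1.276e-2
WC_female	ivw	18	0.5738	0.2112	1.775	1.173	2.685	6.596e-3
BMIadj_WC_female	egger	24	0.6659	0.7861	1.946	0.417	9.085	4.061e-1
BMIadj_WC_female	weighted_median	24	0.2865	0.2213	1.332	0.863	2.055	1.955e-1
BMIadj_WC_female	ivw	24	0.3255	0.1774	1.385	0.978	1.961	6.650e-2
WHR_female	egger	20	-0.7122	1.1173	0.491	0.055	4.383	5.319e-1
WHR_female	weighted_median	20	0.2172	0.2383	1.243	0.779	1.982	3.619e-1
WHR_female	ivw	20	0.3912	0.2220	1.479	0.957	2.285	7.806e-2
BMIadj_WHR_female	egger	32	0.0927	0.5285	1.097	0.389	3.091	8.620e-1
BMIadj_WHR_female	weighted_median	32	0.1742	0.1743	1.190	0.846	1.675	3.175e-1
BMIadj_WHR_female	ivw	32	0.2089	0.1387	1.232	0.939	1.617	1.322e-1
T2DM	egger	8	0.0244	0.1823	1.025	0.717	1.465	8.979e-1
T2DM	weighted_median	8	-0.0285	0.0355	0.972	0.907	1.042	4.208e-1
T2DM	ivw	8	-0.0325	0.0384	0.968	0.898	1.044	3.962e-1
CAD	egger	10	-0.0226	0.1086	0.978	0.790	1.210	8.403e-1
CAD	weighted_median	10	-0.0474	0.0283	0.954	0.902	1.008	9.473e-2
CAD	ivw	10	-0.0349	0.0228	0.966	0.923	1.010	1.258e-1
BC	egger	9	0.0441	0.1278	1.045	0.814	1.343	7.403e-1
BC	weighted_median	9	0.0727	0.0268	1.075	1.020	1.133	6.697e-3
BC	ivw	9	0.0646	0.0277	1.067	1.010	1.126	1.950e-2
ERpos_BC	egger	9	0.0859	0.1501	1.090	0.812	1.462	5.850e-1
ERpos_BC	weighted_median	9	0.0981	0.0341	1.103	1.032	1.179	4.015e-3
ERpos_BC	ivw	9	0.0862	0.0324	1.090	1.023	1.161	7.900e-3
ERneg_BC	egger	9	-0.0564	0.1630	0.945	0.687	1.301	7.394e-1
ERneg_BC	weighted_median	9	0.0168	0.0399	1.017	0.940	1.100	6.744e-1
ERneg_BC	ivw	9	0.0605	0.0368	1.062	0.988	1.142	1.001e-1
"""


def reported_mr_estimates() -> pd.DataFrame:
    """Published (beta, SE, OR, 95% CI, p) rows; see module docstring."""
    return pd.read_csv(StringIO(_REPORTED), sep="\t")
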