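"""Regenerate the pinned fixture network YAMLs under src/bayesboost/data/.

Run from the repository root. The committed YAMLs are the source of truth;

this script documents how they were authored (docs/methods.md explains the
design constants) and expands the logistic risk formulas into dense tables,
serializing them through the package's own validation.
"""
import numpy as np
from bayesboost.bayesnet import BayesianNetwork, Cpt, Dag

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))

ETH = ("White or not stated", "Indian", "Pakistani", "Bangladeshi", "Other Asian",
       "Black Caribbean", "Black African", "Chinese", "Other ethnic group", "Mixed")
REGION = ("London", "South Central", "North West", "North East", "Yorkshire",
          "East Midlands", "West Midlands", "East of England", "South East", "South West")
AGE = ("[25,40)", "[40,50)", "[50,60)", "[60,70)", "[70,80)")
SMOKE = ("never", "ex", "current")
BMI = ("[18,23)", "[23,27)", "[27,31)", "[31,36)", "[36,45)")
SBP = ("[100,120)", "[120,135)", "[135,150)", "[150,165)", "[165,190)")
BIN01 = ("0", "1")

# CVD-like fixture -----------------------------------------------------------
# Risk elevations and group differences are amplified relative to textbook
# epidemiology so the dependencies remain information-criterion-learnable at
# 10^4-row scale (the datasets this emulates have ~5x10^5 rows).
eth_p = [0.78, 0.12, 0.02, 0.01, 0.012, 0.012, 0.012, 0.01, 0.012, 0.012]
region_p = [0.16, 0.12] + [0.09] * 8
age_p = [0.25, 0.20, 0.20, 0.20, 0.15]
base_smoke = {"F": [0.55, 0.25, 0.20], "M": [0.45, 0.25, 0.30]}
# mass moved from never- to current-smoker per ethnicity
eth_smoke_shift = [0.0] * 10
base_bmi_by_age = [
    [0.30, 0.35, 0.20, 0.10, 0.05],
    [0.22, 0.33, 0.25, 0.13, 0.07],
    [0.18, 0.30, 0.27, 0.16, 0.09],
    [0.15, 0.28, 0.30, 0.18, 0.09],
    [0.15, 0.30, 0.30, 0.17, 0.08],
]
# +1 pushes BMI mass one band up, -1 one band down
eth_bmi_shift = [0] * 10
sbp_by_age = [
    [0.35, 0.35, 0.18, 0.08, 0.04],
    [0.28, 0.34, 0.22, 0.11, 0.05],
    [0.20, 0.32, 0.26, 0.15, 0.07],
    [0.14, 0.28, 0.30, 0.19, 0.09],
    [0.10, 0.24, 0.31, 0.23, 0.12],
]
eth_stroke = [0.0, 2.4, 1.9, 1.9, 1.6, 1.2, 1.2, 0.3, 0.2, 0.7]
smoke_eff = [0.0, 0.3, 0.8]
eth_t2d = [0.0, 1.6, 1.6, 1.6, 1.4, 0.9, 0.9, 0.4, 0.0, 0.4]

def binary_rows(parent_dims, logit_fn):
    rows = []
    for j in range(int(np.prod(parent_dims))):
        cfg = np.unravel_index(j, parent_dims)
        p1 = float(sigmoid(logit_fn(*cfg)))
        rows.append([1.0 - p1, p1])
    return rows

def shift_dist(p, s):
    p = np.asarray(p, dtype=float)
    if s == 0:
        return p
    out = np.zeros_like(p)
    if s > 0:
        for k in range(len(p)):
            out[min(k + 1, len(p) - 1)] += 0.55 * p[k]
            out[k] += 0.45 * p[k]
    else:
        for k in range(len(p)):
            out[max(k - 1, 0)] += 0.55 * p[k]
            out[k] += 0.45 * p[k]
    return out / out.sum()

smoke_rows = []
for g in ("F", "M"):
    for e in range(10):
        never, ex, cur = base_smoke[g]
        d = eth_smoke_shift[e]
        smoke_rows.append([never - d, ex, cur + d])
bmi_rows = []
for e in range(10):
    for a in range(5):
        bmi_rows.append(list(shift_dist(base_bmi_by_age[a], eth_bmi_shift[e])))

nodes = ["gender", "ethnicity", "region", "age", "smoking", "bmi", "sbp",
         "stroke_heart_attack", "atrial_fibrillation", "type2_diabetes"]
edges = (("gender", "smoking"), ("ethnicity", "smoking"),
         ("age", "bmi"), ("ethnicity", "bmi"), ("age", "sbp"),
         ("ethnicity", "stroke_heart_attack"), ("age", "stroke_heart_attack"),
         ("smoking", "stroke_heart_attack"), ("sbp", "stroke_heart_attack"),
         ("gender", "atrial_fibrillation"), ("age", "atrial_fibrillation"),
         ("ethnicity", "type2_diabetes"), ("bmi", "type2_diabetes"))
dag = Dag(tuple(nodes), edges)
levels = {
    "gender": ("F", "M"), "ethnicity": ETH, "region": REGION, "age": AGE,
    "smoking": SMOKE, "bmi": BMI, "sbp": SBP,
    "stroke_heart_attack": BIN01, "atrial_fibrillation": BIN01, "type2_diabetes": BIN01,
}
cpts = {
    "gender": Cpt("gender", (), np.array([[0.51, 0.49]])),
    "ethnicity": Cpt("ethnicity", (), np.array([eth_p])),
    "region": Cpt("region", (), np.array([region_p])),
    "age": Cpt("age", (), np.array([age_p])),
    "smoking": Cpt("smoking", ("gender", "ethnicity"), np.array(smoke_rows)),
    "bmi": Cpt("bmi", ("ethnicity", "age"), np.array(bmi_rows)),
    "sbp": Cpt("sbp", ("age",), np.array(sbp_by_age)),
    "stroke_heart_attack": Cpt(
        "stroke_heart_attack", ("ethnicity", "age", "smoking", "sbp"),
        np.array(binary_rows((10, 5, 3, 5),
                 lambda e, a, s, sb: -5.1 + 0.5 * a + smoke_eff[s] + 0.8 * sb + eth_stroke[e]))),
    "atrial_fibrillation": Cpt(
        "atrial_fibrillation", ("gender", "age"),
        np.array(binary_rows((2, 5), lambda g, a: -3.9 + 0.62 * a + 0.3 * g))),
    "type2_diabetes": Cpt(
        "type2_diabetes", ("ethnicity", "bmi"),
        np.array(binary_rows((10, 5), lambda e, b: -3.3 + 0.5 * b + eth_t2d[e]))),
}
cvd = BayesianNetwork(dag=dag, cpts=cpts, level_index=levels)
cvd.to_yaml("src/bayesboost/data/cvd_like.yaml")

# Covid-like fixture ---------------------------------------------------------
CAGE = ("[18,35)", "[35,50)", "[50,65)", "[65,80)", "[80,95)")
nodes = ["gender", "region", "age", "covid_diagnosis"]
dag = Dag(tuple(nodes), (("gender", "covid_diagnosis"), ("age", "covid_diagnosis")))
levels = {"gender": ("F", "M"), "region": REGION, "age": CAGE, "covid_diagnosis": BIN01}
cpts = {
    "gender": Cpt("gender", (), np.array([[0.52, 0.48]])),
    "region": Cpt("region", (), np.array([region_p])),
    "age": Cpt("age", (), np.array([[0.28, 0.26, 0.22, 0.16, 0.08]])),
    "covid_diagnosis": Cpt(
        "covid_diagnosis", ("gender", "age"),
        np.array(binary_rows((2, 5), lambda g, a: -2.6 + 0.35 * a + 0.15 * g))),
}
covid = BayesianNetwork(dag=dag, cpts=cpts, level_index=levels)
covid.to_yaml("src/bayesboost/data/covid_like.yaml")

# Toy oracle network ---------------------------------------------------------
dag = Dag(("A", "B"), (("A", "B"),))
toy = BayesianNetwork(
    dag=dag,
    cpts={
        "A": Cpt("A", (), np.array([[0.7, 0.3]])),
        "B": Cpt("B", ("A",), np.array([[0.8, 0.2], [0.2, 0.8]])),
    },
    level_index={"A": ("0", "1"), "B": ("0", "1")},
)
toy.to_yaml("src/bayesboost/data/toy_ab.yaml")
print("wrote fixture YAMLs")
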