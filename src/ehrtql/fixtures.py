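"""Canonical published TQL programs, used as the conformance fixtures.

Four worked queries: (1) type II diabetics on glipizide who went on to have
a stroke within 3 months; (2) a HEDIS quality measure on the avoidance of
antibiotics to treat acute bronchitis; (3) clinical-trial inclusion criteria
(women ≥70 with breast carcinoma in situ and no prior invasive breast
cancer); (4) labeling type 2 diabetics — and the time they first met the
definition — for machine-learning training data.

The texts are kept verbatim as printed (juxtaposed ``var`` keywords, mixed
case, spacing), with typographic quotes normalised to ASCII.
"""

from __future__ import annotations

from .parser import QueryProgram, parse_program

BOX1_DIABETES_STROKE = '''\
varstroke= ICD9="434.91"
varmale_patients_over_65 = INTERSECT(GENDER="male", AGE(65 YEARS, MAX))
varglipizide= RX = 310490
varno_history_of_stroke= NO HISTORY OF ($stroke)
vardiabetes= FIRST MENTION(UNION(COUNT(ICD9="250.00", 2, MAX),
COUNT(LABS("4548-4 [%]", 8, MAX), 2, MAX)))
vardiabetes_no_hx_stroke= INTERSECT($diabetes,$no_history_of_stroke)
vardiabetes_then_glipizide= SEQUENCE($diabetes_no_hx_stroke,$glipizide*)
varglipizide_then_stroke= SEQUENCE($diabetes_then_glipizide,$stroke*)+(-3 MONTHS, 0)
INTERSECT($male_patients_over_65,$glipizide_then_stroke)
'''

BOX2_BRONCHITIS_HEDIS = '''\
varage= AGE(18 YEARS, 64 YEARS)
varbronchitis= ICD9="466.0"
varhiv= ICD9="042"
varmal_neo= UNION(ICD9="140", ICD9="141", ICD9="142", ICD9="143", ICD9="144", ICD9="145", ICD9="146", ICD9="147", ICD9="148", ICD9="149", ICD9="150", ICD9="151", ICD9="152", ICD9="153", ICD9="154", ICD9="155", ICD9="156", ICD9="157", ICD9="158", ICD9="159", ICD9="160", ICD9="161", ICD9="162", ICD9="163", ICD9="164", ICD9="165", ICD9="170", ICD9="171", ICD9="172", ICD9="173", ICD9="174", ICD9="176", ICD9="180", ICD9="182", ICD9="183", ICD9="184", ICD9="186", ICD9="187", ICD9="188", ICD9="189", ICD9="190", ICD9="191", ICD9="192", ICD9="194", ICD9="195", ICD9="196", ICD9="197", ICD9="198", ICD9="199", ICD9="200", ICD9="201", ICD9="202", ICD9="203", ICD9="204", ICD9="205", ICD9="206", ICD9="207", ICD9="208", ICD9="209")
varemphysema= UNION(ICD9="492")
varcopd= UNION(ICD9="493.2", ICD9="496")
varcystic_fibrosis= UNION(ICD9="277.0")
varccvs= UNION(ICD9="279", ICD9="491", ICD9="494", ICD9="495", ICD9="500", ICD9="506", ICD9="507", ICD9="508", ICD9="510", ICD9="511", ICD9="512", ICD9="513", ICD9="516", ICD9="517", ICD9="518", ICD9="519", ICD9="010", ICD9="011", ICD9="012", ICD9="013", ICD9="014", ICD9="015", ICD9="016", ICD9="017", ICD9="018")
varcdvs= UNION(ICD9="001", ICD9="002", ICD9="003", ICD9="004", ICD9="005", ICD9="006", ICD9="007", ICD9="008", ICD9="009", ICD9="033", ICD9="041.9", ICD9="088", ICD9="382", ICD9="461", ICD9="462", ICD9="034.0", ICD9="473", ICD9="464.1", ICD9="464.2", ICD9="464.3", ICD9="474", ICD9="478.21", ICD9="478.24", ICD9="478.29", ICD9="478.71", ICD9="478.79", ICD9="478.9", ICD9="601", ICD9="383", ICD9="681", ICD9="682", ICD9="730", ICD9="686", ICD9="482", ICD9="483", ICD9="484", ICD9="486", ICD9="098", ICD9="099", ICD9="V01.6", ICD9="090", ICD9="091", ICD9="092", ICD9="093", ICD9="094", ICD9="095", ICD9="096",ICD9="097", ICD9="098", ICD9="099", ICD9="078.88", ICD9="079.88")
varantibiotic= UNION(RX = 641, RX = 142438, RX = 10109, RX = 10627, RX = 723,RX = 733, RX = 8339, RX = 10591, RX = 2177, RX = 2180, RX = 2231, RX = 20481, RX = 274786, RX = 2582, RX = 18631, RX = 21212, RX = 4053, RX = 1272, RX = 2348, RX = 229369, RX = 22299, RX = 190376, RX = 6922, RX = 11124, RX = 7980, RX = 7984, RX = 3356, RX = 7233, RX = 7773, RX = 9384, RX = 2176, RX = 2187, RX = 19552, RX = 2189, RX = 2194, RX = 10171, RX = 10180, RX = 3640, RX = 6980, RX = 10395, RX = 25037, RX = 83682, RX = 25033, RX = 2186, RX = 20489, RX = 2191, RX = 20492, RX = 2193, RX = 4550, RX = 7454, RX = 10829)
varbronchitis_cohort= INTERSECT($bronchitis,$age)
varno_ccvs= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($ccvs)),SEQUENCE($ccvs,$bronchitis_cohort*)-(-1 YEAR, 1 DAY))
varno_cdvs= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($cdvs)),SEQUENCE($cdvs,$bronchitis_cohort*)-(-30 DAYS, 8 DAYS))
varno_emphysema= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($emphysema)), SEQUENCE($emphysema,$bronchitis_cohort*)-(-1 YEAR, 1 DAY))
varno_copd= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($copd)), SEQUENCE($copd,$bronchitis_cohort*)-(-1 YEAR, 1 DAY))
varno_cf= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($cystic_fibrosis)), SEQUENCE($cystic_fibrosis,$bronchitis_cohort*)-(-1 YEAR, 1 DAY))
varno_hiv= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($hiv)), SEQUENCE($hiv,$bronchitis_cohort*)-(-1 YEAR, 1 DAY))
varno_mal_neo= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($mal_neo)), SEQUENCE($mal_neo,$bronchitis_cohort*)-(-1 YEAR, 1 DAY))
varno_antibiotic= UNION(INTERSECT($bronchitis_cohort, NEVER HAD($antibiotic)), SEQUENCE($antibiotic,$bronchitis_cohort*)-(-1 MONTH, -1 DAY))
vardenominator= INTERSECT($no_ccvs,$no_cdvs,$no_emphysema,$no_copd,$no_cf,$no_hiv,$no_mal_neo,$no_antibiotic)
varbronchitis_then_antibiotic= SEQUENCE($denominator,$antibiotic*) + (-3 DAYS, 0 DAYS)
varnumerator= DIFF($denominator,$bronchitis_then_antibiotic)
$numerator
'''

BOX3_BREAST_CA_TRIAL = '''\
varage= AGE(70 YEARS, MAX)
varfemale= GENDER="FEMALE"
varbcis= INTERSECT(ICD9="233.0", NO HISTORY OF(ICD9="174"))
INTERSECT($bcis,$age,$female)
'''

BOX4_T2D_LABELS = '''\
vart2d= FIRST MENTION(UNION(COUNT(ICD9="250.00", 2, MAX), COUNT(LABS("4548-4 [%]", 8, MAX), 2, MAX)))
vart1d= OR(ICD9="250.01", ICD9="250.03")
vart2d_no_t1d= INTERSECT($t2d, NOT($t1d))
EXPORT($t2d_no_t1d, TIME=$t2d_no_t1d, "T2D"=$t2d_no_t1d)
'''

BOXES = {
    1: BOX1_DIABETES_STROKE,
    2: BOX2_BRONCHITIS_HEDIS,
    3: BOX3_BREAST_CA_TRIAL,
    4: BOX4_T2D_LABELS,
}


def box_text(n: int) -> str:
    """TQL source of fixture query ``n`` (1–4)."""
    return BOXES[n]


def box_program(n: int) -> QueryProgram:
    """Parsed fixture query ``n``."""
    return parse_program(BOXES[n])
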