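"""Published figures from the 2012-2018 Shiretoko Peninsula female
brown-bear monitoring study, used as worked-example inputs.

These numbers are inputs to arithmetic cross-checks (count
bookkeeping, Akaike-weight recomputation) and anchors for the synthetic
generator's default scenario; the pipeline never needs them to run.
"""

#: Scats collected per month, June-October, all years pooled.
MONTHLY_SCAT_COUNTS = {6: 267, 7: 403, 8: 552, 9: 507, 10: 350}

#: Printed study total and its split by analysis method.
TOTAL_SCATS = 2079
VISUAL_SCATS_2012 = 315
POINTFRAME_SCATS = 1764

#: Point-frame sample sizes per month in the seasonal-diet table.
POINTFRAME_MONTHLY_N = {6: 242, 7: 308, 8: 476, 9: 466, 10: 272}

#: Delta-AICc values of the 13 candidate body-condition models, in
#: ranked order, and the printed Akaike weights of the top two.
DELTA_AICC = (0.0, 0.7, 3.0, 3.1, 4.8, 5.2, 5.8, 5.8, 21.2, 25.4, 27.1, 27.4, 29.0)
TOP_TWO_WEIGHTS = (0.4, 0.3)

#: August pine-nut EDC (%) in the above-average years, and the
#: seven-year mean; September salmon EDC (%) in the high years.
PINE_EDC_HIGH_YEARS = {2013: 47.4, 2014: 47.5, 2016: 47.3, 2018: 42.9}
PINE_EDC_MEAN = 34.9
SALMON_EDC_HIGH_YEARS = {2013: 54.4, 2016: 65.4, 2018: 72.2}
DIET1_YEARS = (2013, 2016, 2018)
DIET2_YEARS = (2012, 2015, 2017)

#: Top-model parametric estimates (log scale): the reproductive-status
#: deficit of females with dependent young, with its standard error.
RST_OFFSET = -0.025
RST_OFFSET_SE = 0.010

#: Study dimensions.
N_BEARS = 12
N_YEARS = 7
N_SESSIONS = 8
N_PHOTOS = 1226
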