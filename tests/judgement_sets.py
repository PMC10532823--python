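"""Published parcel lists for the four judgement sub-analyses.

Hemisphere-tagged multimodal-parcellation names reported for the moral (MJ),
social (SJ), risk (RJ) and interpersonal (IJ) judgement meta-analyses; used
as fixed inputs to the contrast stage.
"""

MJ = {
    # left: superior frontal, inferior parietal, precuneus, posterior cingulate
    "L_9m", "L_d32", "L_PGi", "L_TPOJ2", "L_STV", "L_31pv", "L_31pd",
    "L_7m", "L_d23ab", "L_v23ab",
    # right: superior frontal, precuneus, temporal
    "R_9m", "R_d32", "R_7m", "R_TE1a", "R_STGa", "R_STSva", "R_STSda", "R_TGd",
}

SJ = {
    # left-dominant frontal / supplementary motor / insular / opercular
    "L_47s", "L_47I", "L_47m", "L_45", "L_8BM", "L_SCEF", "L_SFL", "L_AVI", "L_FOP4",
    # right frontal / insular / temporal limbic
    "R_pOFC", "R_8BM", "R_Pir", "R_EC", "R_amygdala",
}

RJ = {
    # right frontoparietal + cingulate
    "R_PFm", "R_IP2", "R_AIP", "R_LIPd", "R_p32pr", "R_a24pr",
    "R_a32pr", "R_8BM", "R_p9-46v", "R_IFSp", "R_46",
    # left insula
    "L_MI", "L_AAIC",
}

IJ = {
    # right cingulate / frontal / parietal / insula
    "R_p32pr", "R_a24pr", "R_p24", "R_33pr", "R_8BM", "R_SCEF", "R_a32pr",
    "R_d32", "R_MIP", "R_LIPd", "R_IP1", "R_IP2", "R_FOP5", "R_FOP4",
    "R_MI", "R_AVI", "R_AAIC",
    # left insula / operculum
    "L_MI", "L_FOP4",
}

ALL_SETS = {"MJ": MJ, "SJ": SJ, "RJ": RJ, "IJ": IJ}
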