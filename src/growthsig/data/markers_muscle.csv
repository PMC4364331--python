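gene,cell_type,sign,source
NES,pericyte_type2,+,pericyte_marker_literature
NES,endothelial,+,endothelial_marker_literature
NES,satellite_committed,-,satellite_marker_literature
CSPG4,pericyte_type2,+,pericyte_marker_literature
CSPG4,pericyte_type1,+,pericyte_marker_literature
CSPG4,endothelial,-,pericyte_marker_literature
MCAM,pericyte_type2,+,pericyte_marker_literature
MCAM,pericyte_type1,+,pericyte_marker_literature
MCAM,endothelial,+,endothelial_marker_literature
PDGFRB,pericyte_type1,+,pericyte_marker_literature
PDGFRB,pericyte_type2,+,pericyte_marker_literature
PDGFRA,pericyte_type1,+,fap_marker_literature
PDGFRA,fap,+,fap_marker_literature
CD34,satellite_self_renewing,+,satellite_marker_literature
CD34,endothelial,+,endothelial_marker_literature
CD34,fap,+,fap_marker_literature
CD34,pericyte_type1,-,pericyte_marker_literature
SCA1,fap,+,fap_marker_literature
SCA1,satellite_committed,-,satellite_marker_literature
PECAM1,endothelial,+,endothelial_marker_literature
PECAM1,fap,-,fap_marker_literature
PAX7,satellite_self_renewing,+,satellite_marker_literature
PAX7,satellite_committed,+,satellite_marker_literature
PAX7,myotube,-,satellite_marker_literature
MYF5,satellite_committed,+,satellite_marker_literature
MYF5,myoblast,+,satellite_marker_literature
MYF5,satellite_self_renewing,-,satellite_marker_literature
ITGB1,satellite_self_renewing,+,satellite_marker_literature
ITGB1,pericyte_type2,+,pericyte_marker_literature
CD24,myoblast,+,satellite_marker_literature
CDH5,endothelial,+,endothelial_marker_literature
TEK,endothelial,+,endothelial_marker_literature
SOX8,satellite_self_renewing,+,satellite_marker_literature
SOX8,endothelial,+?,cluster_reattribution
WISP2,preadipocyte,+?,adipogenesis_marker_literature
WISP2,fibroblast,+,fibroblast_marker_literature
ZNF423,preadipocyte,+,adipogenesis_marker_literature
ZNF423,adipocyte,+,adipogenesis_marker_literature
CEBPA,preadipocyte,+,adipogenesis_marker_literature
CEBPA,adipocyte,+,adipogenesis_marker_literature
PPARG,preadipocyte,+,adipogenesis_marker_literature
PPARG,adipocyte,+,adipogenesis_marker_literature
ACTA2,pericyte_type1,+,pericyte_marker_literature
ACTA2,myotube,-,pericyte_marker_literature
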