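round,field,vignette,score
1,pressure_relief,V1,0
1,pressure_relief,V2,0
1,pressure_relief,V3,2
1,pressure_relief,V4,3
1,nutritional_management,V1,0
1,nutritional_management,V2,0
1,nutritional_management,V3,0
1,nutritional_management,V4,3
1,shear_relief,V1,0
1,shear_relief,V2,0
1,shear_relief,V3,0
1,shear_relief,V4,0
1,moisture_management,V1,0
1,moisture_management,V2,0
1,moisture_management,V3,2
1,moisture_management,V4,3
1,wound_dressing_use,V1,0
1,wound_dressing_use,V2,0
1,wound_dressing_use,V3,0
1,wound_dressing_use,V4,0
1,physical_factor,V1,0
1,physical_factor,V2,0
1,physical_factor,V3,0
1,physical_factor,V4,3
1,systemic_disorder,V1,0
1,systemic_disorder,V2,0
1,systemic_disorder,V3,0
1,systemic_disorder,V4,2
1,dressing_selection,V1,0
1,dressing_selection,V2,3
1,dressing_selection,V3,3
1,dressing_selection,V4,3
1,wound_cleansing,V1,0
1,wound_cleansing,V2,0
1,wound_cleansing,V3,0
1,wound_cleansing,V4,3
2,pressure_relief,V1,0
2,pressure_relief,V2,0
2,pressure_relief,V3,0
2,pressure_relief,V4,0
2,nutritional_management,V1,0
2,nutritional_management,V2,0
2,nutritional_management,V3,0
2,nutritional_management,V4,3
2,shear_relief,V1,0
2,shear_relief,V2,0
2,shear_relief,V3,2
2,shear_relief,V4,3
2,moisture_management,V1,0
2,moisture_management,V2,0
2,moisture_management,V3,0
2,moisture_management,V4,0
2,wound_dressing_use,V1,0
2,wound_dressing_use,V2,0
2,wound_dressing_use,V3,0
2,wound_dressing_use,V4,3
2,physical_factor,V1,0
2,physical_factor,V2,0
2,physical_factor,V3,0
2,physical_factor,V4,0
2,systemic_disorder,V1,0
2,systemic_disorder,V2,0
2,systemic_disorder,V3,0
2,systemic_disorder,V4,2
2,dressing_selection,V1,0
2,dressing_selection,V2,2
2,dressing_selection,V3,2
2,dressing_selection,V4,2
2,wound_cleansing,V1,2
2,wound_cleansing,V2,2
2,wound_cleansing,V3,2
2,wound_cleansing,V4,2
3,pressure_relief,V1,0
3,pressure_relief,V2,0
3,pressure_relief,V3,0
3,pressure_relief,V4,0
3,nutritional_management,V1,0
3,nutritional_management,V2,2
3,nutritional_management,V3,3
3,nutritional_management,V4,3
3,shear_relief,V1,0
3,shear_relief,V2,3
3,shear_relief,V3,3
3,shear_relief,V4,3
3,moisture_management,V1,0
3,moisture_management,V2,0
3,moisture_management,V3,2
3,moisture_management,V4,3
3,wound_dressing_use,V1,0
3,wound_dressing_use,V2,0
3,wound_dressing_use,V3,0
3,wound_dressing_use,V4,0
3,physical_factor,V1,0
3,physical_factor,V2,0
3,physical_factor,V3,0
3,physical_factor,V4,0
3,systemic_disorder,V1,0
3,systemic_disorder,V2,0
3,systemic_disorder,V3,2
3,systemic_disorder,V4,3
3,dressing_selection,V1,2
3,dressing_selection,V2,3
3,dressing_selection,V3,3
3,dressing_selection,V4,3
3,wound_cleansing,V1,0
3,wound_cleansing,V2,3
3,wound_cleansing,V3,3
3,wound_cleansing,V4,3
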