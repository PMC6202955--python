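trait,function,type,categories,missing_percent,source
Diet,diet,nominal,Omnivore|Invert feeder|Piscivore|Herbivore|Gelatinous inverts,0.0,literature
Trophic level,diet,discretized,Low|Medium|High|Very high,0.0,database
Common maximum depth (m),habitat,discretized,Reef|Shallow|Ocean|Deep,0.0,new
Maximum depth (m),habitat,discretized,Reef|Shallow|Ocean|Deep|Bathy,0.0,new
Temperature preference,habitat,nominal,Deep|Temperate|Subtropical|Tropical,0.0,database
Vertical habitat,habitat,nominal,Reef|Pelagic|Demersal|Benthopelagic|Bathypelagic|Bathydemersal,0.0,database
Horizontal habitat,habitat,nominal,Coast|Neritic|Ocean,0.0,database
Caudal fin shape,morphology,nominal,Forked|Rounded|Truncated|Emarginate|Heterocercal|Continuous|Lanceolate,0.0,literature
Swimming mode,morphology,nominal,BCF|MPF,0.0,literature
Body form,morphology,nominal,Compressed|Cylindrical|Eel|Flat|Fusiform,0.0,literature
Eye position,morphology,nominal,Mid|Side|Top,0.0,literature
Oral gape position,morphology,nominal,Subterminal|Terminal|Hyper-protusable|Inferior|Snout projecting|Lower jaw projecting|Tubular,0.0,literature
Maximum length (cm),morphology,discretized,Small|Medium|Large|Very large,0.0,literature
Reproductive strategy,life_history,nominal,Oviviparous|Ovovparous|Viviparous,1.7,literature
Sexual differentiation,life_history,nominal,Gonochoristic|Hermaphrodite,1.7,literature
Migration,life_history,nominal,Anadromous|Catadromous|Oceanic|None,12.1,literature
Parental care,life_history,nominal,None|Paternal|RDP|Sheltered,2.6,literature
Egg attachment,life_history,nominal,Pelagic|Benthic|Adhesive|None,7.8,literature
Reproduction location,life_history,nominal,Bay|Ocean|River,23.3,literature
Gregariousness,life_history,nominal,Faculative|Obligatory|Solitary,18.1,literature
Population doubling,life_history,nominal,High|Medium|Low|Very low,12.1,database
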