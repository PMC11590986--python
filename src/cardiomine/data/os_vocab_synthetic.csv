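descriptor_id,name,phase,subcategory
D017382,Reactive Oxygen Species,IOS,reactive oxygen species
D013481,Superoxides,IOS,reactive oxygen species
D006861,Hydrogen Peroxide,IOS,reactive oxygen species
D017665,Hydroxyl Radical,IOS,reactive oxygen species
D026082,Singlet Oxygen,IOS,reactive oxygen species
D005609,Free Radicals,IOS,reactive oxygen species
D009569,Nitric Oxide,IOS,reactive nitrogen species
D030421,Peroxynitrous Acid,IOS,reactive nitrogen species
D059085,Reactive Nitrogen Species,IOS,reactive nitrogen species
D009585,Nitrogen Dioxide,IOS,reactive nitrogen species
D000447,Aldehydes,IOS,reactive aldehydes
D000171,Acrolein,IOS,reactive aldehydes
D005978,Glutathione,MOS,redox metabolites
D019803,Glutathione Disulfide,MOS,redox metabolites
D009243,NAD,MOS,redox metabolites
D009249,NADP,MOS,redox metabolites
D014451,Ubiquinone,MOS,redox metabolites
D013817,Thioctic Acid,MOS,redox metabolites
D014527,Uric Acid,MOS,redox metabolites
D001663,Bilirubin,MOS,redox metabolites
D008550,Melatonin,MOS,redox metabolites
D003545,Cysteine,MOS,redox metabolites
D000975,Antioxidants,MOS,antioxidants
D001205,Ascorbic Acid,MOS,antioxidants
D014810,Vitamin E,MOS,antioxidants
D014801,Vitamin A,MOS,antioxidants
D024502,alpha-Tocopherol,MOS,antioxidants
D019207,beta Carotene,MOS,antioxidants
D002338,Carotenoids,MOS,antioxidants
D005419,Flavonoids,MOS,antioxidants
D059808,Polyphenols,MOS,antioxidants
D000077185,Resveratrol,MOS,antioxidants
D003474,Curcumin,MOS,antioxidants
D012643,Selenium,MOS,antioxidants
D015032,Zinc,MOS,antioxidants
D005978,Glutathione,MOS,antioxidants
D910001,Synthetic Antioxidant Compound 1,MOS,antioxidants
D910002,Synthetic Antioxidant Compound 2,MOS,antioxidants
D910003,Synthetic Antioxidant Compound 3,MOS,antioxidants
D910004,Synthetic Antioxidant Compound 4,MOS,antioxidants
D910005,Synthetic Antioxidant Compound 5,MOS,antioxidants
D910006,Synthetic Antioxidant Compound 6,MOS,antioxidants
D013482,Superoxide Dismutase,MOS,antioxidant enzymes
D002374,Catalase,MOS,antioxidant enzymes
D005979,Glutathione Peroxidase,MOS,antioxidant enzymes
D005982,Glutathione Transferase,MOS,antioxidant enzymes
D005980,Glutathione Reductase,MOS,antioxidant enzymes
D006442,Heme Oxygenase (Decyclizing),MOS,antioxidant enzymes
D054464,Peroxiredoxins,MOS,antioxidant enzymes
D010544,Peroxidases,MOS,antioxidant enzymes
D016660,NAD(P)H Dehydrogenase (Quinone),MOS,antioxidant enzymes
D911001,Synthetic Redox Enzyme 1,MOS,antioxidant enzymes
D911002,Synthetic Redox Enzyme 2,MOS,antioxidant enzymes
D911003,Synthetic Redox Enzyme 3,MOS,antioxidant enzymes
D911004,Synthetic Redox Enzyme 4,MOS,antioxidant enzymes
D911005,Synthetic Redox Enzyme 5,MOS,antioxidant enzymes
D911006,Synthetic Redox Enzyme 6,MOS,antioxidant enzymes
D013879,Thioredoxins,MOS,redox regulating proteins
D054477,Glutaredoxins,MOS,redox regulating proteins
D051267,NF-E2-Related Factor 2,MOS,redox regulating proteins
D037761,Sirtuins,MOS,redox regulating proteins
D008668,Metallothionein,MOS,redox regulating proteins
D013879,Thioredoxins,MOS,redox regulating proteins
D912001,Synthetic Redox Regulator 1,MOS,redox regulating proteins
D912002,Synthetic Redox Regulator 2,MOS,redox regulating proteins
D912003,Synthetic Redox Regulator 3,MOS,redox regulating proteins
D912004,Synthetic Redox Regulator 4,MOS,redox regulating proteins
D912005,Synthetic Redox Regulator 5,MOS,redox regulating proteins
D912006,Synthetic Redox Regulator 6,MOS,redox regulating proteins
D912007,Synthetic Redox Regulator 7,MOS,redox regulating proteins
D912008,Synthetic Redox Regulator 8,MOS,redox regulating proteins
D050939,Protein Carbonylation,OOS,protein oxidation
D059829,Protein S-Nitrosylation,OOS,protein oxidation
D008315,Malondialdehyde,OOS,lipid peroxidation products
D015764,Lipid Peroxides,OOS,lipid peroxidation products
D048588,8-Hydroxy-2'-Deoxyguanosine,OOS,oxidative DNA damage
D913001,8-Nitroguanine,OOS,nitrative DNA damage
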