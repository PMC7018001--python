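# Les Miserables character coappearance network (77 nodes, 254 edges, weighted)
Napoleon Myriel 1
Myriel MlleBaptistine 8
Myriel MmeMagloire 10
Myriel CountessDeLo 1
Myriel Geborand 1
Myriel Champtercier 1
Myriel Cravatte 1
Myriel Count 2
Myriel OldMan 1
Myriel Valjean 5
MlleBaptistine MmeMagloire 6
MlleBaptistine Valjean 3
MmeMagloire Valjean 3
Valjean Labarre 1
Valjean Marguerite 1
Valjean MmeDeR 1
Valjean Isabeau 1
Valjean Gervais 1
Valjean Fantine 9
Valjean MmeThenardier 7
Valjean Thenardier 12
Valjean Cosette 31
Valjean Javert 17
Valjean Fauchelevent 8
Valjean Bamatabois 2
Valjean Simplice 3
Valjean Scaufflaire 1
Valjean Woman1 2
Valjean Judge 3
Valjean Champmathieu 3
Valjean Brevet 2
Valjean Chenildieu 2
Valjean Cochepaille 2
Valjean Woman2 3
Valjean MotherInnocent 1
Valjean Gavroche 1
Valjean Gillenormand 2
Valjean MlleGillenormand 2
Valjean Marius 19
Valjean Enjolras 4
Valjean Bossuet 1
Valjean Gueulemer 1
Valjean Babet 1
Valjean Claquesous 1
Valjean Montparnasse 1
Valjean Toussaint 1
Marguerite Fantine 2
Listolier Tholomyes 4
Listolier Fameuil 4
Listolier Blacheville 4
Listolier Favourite 3
Listolier Dahlia 3
Listolier Zephine 3
Listolier Fantine 3
Tholomyes Fameuil 4
Tholomyes Blacheville 4
Tholomyes Favourite 3
Tholomyes Dahlia 3
Tholomyes Zephine 3
Tholomyes Fantine 3
Tholomyes Cosette 1
Tholomyes Marius 1
Fameuil Blacheville 4
Fameuil Favourite 3
Fameuil Dahlia 3
Fameuil Zephine 3
Fameuil Fantine 3
Blacheville Favourite 4
Blacheville Dahlia 3
Blacheville Zephine 3
Blacheville Fantine 3
Favourite Dahlia 5
Favourite Zephine 4
Favourite Fantine 4
Dahlia Zephine 4
Dahlia Fantine 4
Zephine Fantine 4
Fantine MmeThenardier 2
Fantine Thenardier 1
Fantine Javert 5
Fantine Bamatabois 1
Fantine Perpetue 1
Fantine Simplice 2
MmeThenardier Thenardier 13
MmeThenardier Cosette 4
MmeThenardier Javert 1
MmeThenardier Eponine 2
MmeThenardier Anzelma 1
MmeThenardier Magnon 1
MmeThenardier Gueulemer 1
MmeThenardier Babet 1
MmeThenardier Claquesous 1
Thenardier Cosette 1
Thenardier Javert 5
Thenardier Pontmercy 1
Thenardier Boulatruelle 1
Thenardier Eponine 3
Thenardier Anzelma 2
Thenardier Gavroche 1
Thenardier Marius 2
Thenardier Gueulemer 5
Thenardier Babet 6
Thenardier Claquesous 4
Thenardier Montparnasse 1
Thenardier Brujon 3
Cosette Javert 1
Cosette Woman2 1
Cosette Gillenormand 3
Cosette MlleGillenormand 2
Cosette LtGillenormand 1
Cosette Marius 21
Cosette Toussaint 2
Javert Fauchelevent 1
Javert Bamatabois 1
Javert Simplice 1
Javert Woman1 1
Javert Woman2 1
Javert Gavroche 1
Javert Enjolras 6
Javert Gueulemer 1
Javert Babet 2
Javert Claquesous 1
Javert Montparnasse 1
Javert Toussaint 1
Fauchelevent MotherInnocent 3
Fauchelevent Gribier 2
Bamatabois Judge 2
Bamatabois Champmathieu 2
Bamatabois Brevet 1
Bamatabois Chenildieu 1
Bamatabois Cochepaille 1
Perpetue Simplice 2
Judge Champmathieu 3
Judge Brevet 2
Judge Chenildieu 2
Judge Cochepaille 2
Champmathieu Brevet 2
Champmathieu Chenildieu 2
Champmathieu Cochepaille 2
Brevet Chenildieu 2
Brevet Cochepaille 2
Chenildieu Cochepaille 2
Pontmercy MmePontmercy 1
Pontmercy Marius 1
Eponine Anzelma 2
Eponine Marius 5
Eponine Mabeuf 1
Eponine Courfeyrac 1
Eponine Gueulemer 1
Eponine Babet 1
Eponine Claquesous 1
Eponine Montparnasse 1
Eponine Brujon 1
MmeBurgon Jondrette 1
MmeBurgon Gavroche 2
Gavroche Marius 4
Gavroche Mabeuf 1
Gavroche Enjolras 7
Gavroche Combeferre 6
Gavroche Prouvaire 1
Gavroche Feuilly 2
Gavroche Courfeyrac 7
Gavroche Bahorel 5
Gavroche Bossuet 5
Gavroche Joly 3
Gavroche Grantaire 1
Gavroche Gueulemer 1
Gavroche Babet 1
Gavroche Montparnasse 1
Gavroche Child1 2
Gavroche Child2 2
Gavroche Brujon 1
Gavroche MmeHucheloup 1
Gillenormand Magnon 1
Gillenormand MlleGillenormand 9
Gillenormand LtGillenormand 1
Gillenormand Marius 12
Gillenormand BaronessT 1
MlleGillenormand MmePontmercy 1
MlleGillenormand MlleVaubois 1
MlleGillenormand LtGillenormand 2
MlleGillenormand Marius 6
LtGillenormand Marius 1
Marius BaronessT 1
Marius Mabeuf 1
Marius Enjolras 7
Marius Combeferre 5
Marius Feuilly 1
Marius Courfeyrac 9
Marius Bahorel 1
Marius Bossuet 5
Marius Joly 2
Mabeuf Enjolras 1
Mabeuf Combeferre 2
Mabeuf Feuilly 1
Mabeuf Courfeyrac 2
Mabeuf Bahorel 2
Mabeuf Bossuet 1
Mabeuf Joly 1
Mabeuf MotherPlutarch 3
Enjolras Combeferre 15
Enjolras Prouvaire 4
Enjolras Feuilly 6
Enjolras Courfeyrac 17
Enjolras Bahorel 4
Enjolras Bossuet 10
Enjolras Joly 5
Enjolras Grantaire 3
Enjolras Claquesous 1
Enjolras MmeHucheloup 1
Combeferre Prouvaire 2
Combeferre Feuilly 5
Combeferre Courfeyrac 13
Combeferre Bahorel 5
Combeferre Bossuet 9
Combeferre Joly 5
Combeferre Grantaire 1
Prouvaire Feuilly 2
Prouvaire Courfeyrac 3
Prouvaire Bahorel 2
Prouvaire Bossuet 2
Prouvaire Joly 2
Prouvaire Grantaire 1
Feuilly Courfeyrac 6
Feuilly Bahorel 3
Feuilly Bossuet 6
Feuilly Joly 5
Feuilly Grantaire 1
Courfeyrac Bahorel 6
Courfeyrac Bossuet 12
Courfeyrac Joly 5
Courfeyrac Grantaire 2
Courfeyrac MmeHucheloup 1
Bahorel Bossuet 4
Bahorel Joly 5
Bahorel Grantaire 1
Bahorel MmeHucheloup 1
Bossuet Joly 7
Bossuet Grantaire 3
Bossuet MmeHucheloup 1
Joly Grantaire 2
Joly MmeHucheloup 1
Grantaire MmeHucheloup 1
Gueulemer Babet 6
Gueulemer Claquesous 4
Gueulemer Montparnasse 2
Gueulemer Brujon 3
Babet Claquesous 4
Babet Montparnasse 2
Babet Brujon 3
Claquesous Montparnasse 2
Claquesous Brujon 1
Montparnasse Brujon 1
Child1 Child2 3
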