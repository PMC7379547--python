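id,location,F_eur,mc_eur_per_dose,cp_doses,current_doses,d_km,tc_eur_per_km,k_doses_per_trip
B1,"Paris, France",119000,0.12,607776,303888,200,2.5,400
B2,"Madrid, Spain",41000,0.56,55160,27580,300,2.5,400
B3,"Valdepenas, Spain",45000,0.30,88120,44060,200,2.5,400
B4,"Bellaterra, Spain",115000,1.89,10946,5473,200,2.5,400
B5,"Godollo, Hungary",38000,3.88,4124,2062,200,2.5,400
B6,"Thalheim, Germany",338000,0.23,435174,217587,100,2.5,400
B7,"Wageningen, Netherlands",190000,0.05,882470,441235,100,2.5,400
B8,"P. de Mallorca, Spain",36000,0.97,30018,15009,100,2.5,400
B9,"Kenilworth, UK",115000,0.15,551944,275972,500,2.5,400
B10,"Kiev, Ukraine",115000,0.07,292602,146301,100,2.5,400
B11,"Colmenar V., Spain",115000,0.15,335350,167675,200,2.5,400
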