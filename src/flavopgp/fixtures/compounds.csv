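compound_id,name,cas,scaffold,substituents
1,5-Methoxyflavone,42079-78-7,flavone,5:OMe
2,"5,7-Dimethoxyflavone",21392-57-4,flavone,5:OMe;7:OMe
3,"5,3'-Dimethoxyflavone",,flavone,5:OMe;3':OMe
4,"5,7,3'-Trimethoxyflavone",,flavone,5:OMe;7:OMe;3':OMe
5,"5,7,3',4'-Tetramethoxyflavone",855-97-0,flavone,5:OMe;7:OMe;3':OMe;4':OMe
6,Tangertin,481-53-8,flavone,5:OMe;6:OMe;7:OMe;3':OMe;4':OMe
7,Chrysin,480-40-0,flavone,5:OH;7:OH
8,Baicalein,491-67-8,flavone,5:OH;6:OH;7:OH
9,Wogonin,632-85-9,flavone,5:OH;7:OH;8:OMe
10,Apigenin,520-36-5,flavone,5:OH;7:OH;4':OH
11,Luteolin,491-70-3,flavone,5:OH;7:OH;3':OH;4':OH
12,Vitexin,3681-93-4,flavone,5:OH;7:OH;4':OH;8:Cglc
13,Schaftoside,51938-32-0,flavone,5:OH;7:OH;4':OH;6:Cglc;8:Carb
14,Galangin,548-83-4,flavone,3:OH;5:OH;7:OH
15,Kaempferide,491-54-3,flavone,3:OH;5:OH;7:OH;4':OMe
16,Fisetin,528-48-3,flavone,3:OH;7:OH;3':OH;4':OH
17,Quercetin,117-39-5,flavone,3:OH;5:OH;7:OH;3':OH;4':OH
18,Morin,480-16-0,flavone,3:OH;5:OH;7:OH;2':OH;4':OH
19,Isorhamnetin,480-19-3,flavone,3:OH;5:OH;7:OH;4':OH;3':OMe
20,Myricetin,529-44-2,flavone,3:OH;5:OH;7:OH;3':OH;4':OH;5':OH
21,Rutin,153-18-4,flavone,3:ORG;5:OH;7:OH;3':OH;4':OH
22,Liquiritigenin,578-86-9,flavanone,7:OH;4':OH
23,Naringenin,480-41-1,flavanone,5:OH;7:OH;4':OH
24,Hesperetin,520-33-2,flavanone,5:OH;7:OH;3':OH;4':OMe
25,Taxifolin,24198-97-8,flavanonol-like,3:OH;5:OH;7:OH;3':OH;4':OH
26,Dihydromyricetin,27200-12-0,flavanonol-like,3:OH;5:OH;7:OH;3':OH;4':OH;5':OH
27,Silibinin,22888-70-6,flavonolignan,
28,Daidzein,40957-83-3,isoflavone,7:OH;4':OH
29,Puerarin,3681-99-0,isoflavone,7:OH;4':OH;8:Cglc
30,Genistein,446-72-0,isoflavone,5:OH;7:OH;4':OH
31,Biochanin A,491-80-5,isoflavone,5:OH;7:OH;4':OMe
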