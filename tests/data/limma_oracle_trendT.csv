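"gene","logFC","AveExpr","t","P","s2_post","d0","s2_prior"
"g000",1.27989940303958,7.49378872744538,3.88605967658464,0.00148308985219506,0.325427310176753,4.87572176407795,0.214119181707348
"g001",2.25029611027278,5.44952152513807,7.71410565269134,1.41769984523178e-06,0.255287428268111,4.87572176407795,0.174550177060014
"g002",1.6539492256395,7.6330153798496,6.01143071196919,2.46846888763485e-05,0.227096222007896,4.87572176407795,0.22055173557891
"g003",1.325297109435,6.97238753481334,3.37236724669563,0.00423086864421171,0.463316781582915,4.87572176407795,0.193820146086433
"g004",1.31052672597661,3.30845965320332,4.86604378869738,0.00021038195076924,0.217601053361278,4.87572176407795,0.162919423246561
"g005",-0.104823060103313,8.01311144585054,-0.341459599993899,0.737533163454511,0.282719828101097,4.87572176407795,0.239829570603586
"g006",0.107513869459795,6.67598895676065,0.378816399146467,0.710176254756147,0.241653281348796,4.87572176407795,0.185328422993876
"g007",0.0860400318096386,6.54104640684193,0.402544554717076,0.693008608909721,0.137054868342606,4.87572176407795,0.182272753686967
"g008",-0.0826844777939579,2.78925071740146,-0.563299136922545,0.581623335826699,0.0646384686285787,4.87572176407795,0.152763511423134
"g009",-0.259604853332303,4.66488409000656,-0.777385971144912,0.449118120885084,0.334559580913193,4.87572176407795,0.176340617378525
"g010",0.498780929182406,4.15705732168224,1.89963531472554,0.0770454230643404,0.20682377719341,4.87572176407795,0.174522545781438
"g011",-0.237535072279198,7.53434793389209,-1.04384112573941,0.313226229997306,0.155348810887456,4.87572176407795,0.21595343916057
"g012",-0.00287487700566583,6.05973446924663,-0.00981734099055417,0.992297472684094,0.257259867453754,4.87572176407795,0.175723896447089
"g013",-0.170304615355203,6.93864265606322,-0.765067906993244,0.456198118745228,0.148653151570527,4.87572176407795,0.192734784028087
"g014",-0.041221051387035,4.6328686770993,-0.236107982651466,0.816568905168064,0.0914403844057847,4.87572176407795,0.176343121331126
"g015",0.17619437663075,3.40850332741774,0.701796653391339,0.493640671786547,0.189096180127966,4.87572176407795,0.164691882932532
"g016",-0.285799879037064,5.45612109282304,-1.46685370784289,0.163237207587204,0.113886364632833,4.87572176407795,0.174538307611991
"g017",-0.406929406558069,2.46154673235763,-1.19537781071921,0.250648726558213,0.347655436381611,4.87572176407795,0.145944944740777
"g018",-0.19313738329271,6.88891007705242,-0.557785145175557,0.585288175753067,0.35968311675146,4.87572176407795,0.191189536499259
"g019",0.104999162324139,5.96639791899161,0.338803189774833,0.739493069101835,0.288136278330242,4.87572176407795,0.17514697179655
"g020",0.167207022877202,6.54845586724208,0.605458694952854,0.553999944035221,0.228802751316669,4.87572176407795,0.182426820223619
"g021",-0.411688923444097,4.35928268279691,-1.54977278914567,0.1422060594444,0.211701315598196,4.87572176407795,0.175771598628587
"g022",0.101066340667226,7.38302327858691,0.274102112949899,0.787775766534064,0.407858549846695,4.87572176407795,0.209284991748129
"g023",-0.047811792639989,7.41761806243535,-0.284090237677957,0.780257383319302,0.0849725573535907,4.87572176407795,0.210766679637112
"g024",0.313118309446636,6.59922758582347,1.7899819665215,0.0938282626161747,0.091799617262914,4.87572176407795,0.183525728362026
"g025",0.0772505872586844,3.14143633035077,0.420434207950723,0.680178637729506,0.101281178243967,4.87572176407795,0.159801049431768
"g026",0.0542536542305874,4.59472085270971,0.191303417914078,0.850874499782032,0.241286923674702,4.87572176407795,0.176329631878976
"g027",0.40913004778457,2.51499479051013,1.60976269503103,0.128460829681898,0.193785059417096,4.87572176407795,0.147061699655326
"g028",-0.322751069193868,2.80231535547676,-1.94594259262827,0.0708056450576584,0.0825271003405892,4.87572176407795,0.153032176406327
"g029",-0.135651882427792,6.1746960455985,-0.516936134417693,0.612800731452579,0.206585160791324,4.87572176407795,0.176705491681918
"g030",-0.27657158296402,6.56983682114457,-1.51396409225758,0.150990326467958,0.100116397943622,4.87572176407795,0.182880428034435
"g031",-0.580750267447383,7.74598563033359,-1.62012882650074,0.126204672495384,0.385479238992816,4.87572176407795,0.226039345444361
"g032",0.0729065813865507,3.76732487948791,0.218236496806363,0.830210423444468,0.334811186929858,4.87572176407795,0.170277292542806
"g033",-0.242471695474946,4.36170156580268,-1.0368446012043,0.316369732080847,0.164065026088726,4.87572176407795,0.175782085690785
"g034",-0.153763544884649,4.87418872184243,-0.680626751753066,0.506564206955564,0.153112268297934,4.87572176407795,0.176070426668034
"g035",0.556670300852266,2.87312121126954,2.13993834272576,0.0493495038943465,0.203008787537388,4.87572176407795,0.154480514470937
"g036",-0.454231292564236,2.75253792927356,-2.35668898081249,0.0325791079679731,0.111447623579632,4.87572176407795,0.152006485298761
"g037",-0.0644106290702836,4.82676617988055,-0.392475714091564,0.700272994016009,0.0807998881480022,4.87572176407795,0.176164188058697
"g038",-0.164765113728258,3.34361929052781,-0.764276811839675,0.456655169377005,0.139428133334549,4.87572176407795,0.163551292745773
"g039",-0.0132465137779369,5.86449405006766,-0.0284435400852253,0.977686485864807,0.650664556723204,4.87572176407795,0.174715170901227
"g040",0.11382768455379,4.5620209748858,0.296623080654445,0.770855579968468,0.44178114444477,4.87572176407795,0.176302854241041
"g041",0.54232555765441,6.86789179694696,2.00465405455237,0.0635526666785861,0.219564702804101,4.87572176407795,0.19055615185184
"g042",-0.130215535600454,6.16871613323211,-0.448739828104555,0.660087038993714,0.252614120836795,4.87572176407795,0.176646458077096
"g043",0.227425794456901,3.88423944716759,0.606347514229139,0.553425278221916,0.422043768943806,4.87572176407795,0.171777844259004
"g044",0.0497091663749325,7.05535284800705,0.131766947286804,0.89693428982476,0.426954156413768,4.87572176407795,0.196613116733367
"g045",-0.414075004779077,6.40461842308757,-1.19658672995613,0.25019106305737,0.359245156352469,4.87572176407795,0.179728713467796
"g046",0.33293958936224,4.50790715721222,1.40215810625122,0.181390102555411,0.16914460867938,4.87572176407795,0.176225345500579
"g047",-0.255558040322352,3.72966721299872,-1.15881241521463,0.264797554373261,0.145906309991247,4.87572176407795,0.169757103508834
"g048",0.251935682801579,5.96270335233194,1.46969840744273,0.162474908507147,0.0881544364617525,4.87572176407795,0.17512785540313
"g049",-0.508391301392737,2.67849007698386,-1.73395584844361,0.103594212599106,0.257894100358573,4.87572176407795,0.150471856017536
"g050",0.272027324612059,3.01044682981287,0.941534794786344,0.361470745120211,0.250422626877898,4.87572176407795,0.157242680753413
"g051",-0.0748000303693761,2.07659731200935,-0.364259221154986,0.720790228821137,0.126503835669236,4.87572176407795,0.137998852098127
"g052",-0.0627961548344168,6.71976692066241,-0.237384900029204,0.815596505134966,0.209933225061107,4.87572176407795,0.186431392496628
"g053",-0.193317108390991,6.25176958761551,-0.663693676793602,0.517041196762163,0.254522672971434,4.87572176407795,0.177550486957261
"g054",-0.0965840935751674,6.33663090362831,-0.465886691198664,0.648045034198911,0.128935308251658,4.87572176407795,0.17867281784611
"g055",-0.291600181595672,6.69547840236182,-0.946247527501309,0.359140520387189,0.284896634872122,4.87572176407795,0.185812799420692
"g056",0.457950440549417,4.65455157727639,1.40411273272282,0.1808183315693,0.31912017523133,4.87572176407795,0.176342750402303
"g057",-0.301909007217081,5.44412768391007,-1.21072264975355,0.244887290136236,0.186545192235689,4.87572176407795,0.174560118080785
"g058",-0.215406820629117,2.62845584244317,-0.838616514846459,0.414957518808379,0.197930779322444,4.87572176407795,0.149430460083975
"g059",-0.236859378908248,2.6083324653967,-0.654167927139468,0.522989107784237,0.39329998692897,4.87572176407795,0.149010891221098
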